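"""Regression-model validation statistics.

Implements the QSAR validation canon: training R², adjusted R², RMSE, MAE
and Lin's concordance correlation coefficient (CCC); cross-validated Q² by
leave-one-out (via the exact hat-matrix shortcut) and seeded k-fold; and
Y-randomization (response scrambling) as a chance-correlation guard.

Q² is PRESS-based throughout: Q² = 1 − PRESS / SStot with SStot taken about
the full-sample mean, and k-fold PRESS pooled across folds.  CCC uses
population (1/n) moments (Lin 1989); at the small n typical of QSAR the
1/n vs 1/(n−1) choice is visible, so it is documented and fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linear import SingularDesignError, fit_ols

__all__ = [
    "THRESHOLDS",
    "ValidationReport",
    "YRandomizationReport",
    "regression_metrics",
    "q2_loo",
    "q2_kfold",
    "y_randomization",
    "kfold_assignment",
]

# Published acceptability thresholds for a QSAR regression model.
THRESHOLDS = {
    "r2_min": 0.6,
    "q2_min": 0.5,
    "mae_max": 0.6,
    "ccc_min": 0.85,
}


@dataclass
class ValidationReport:
    """Full statistics suite for one fitted model on one dataset."""

    n: int
    p: int
    r2: float
    r2_adjusted: float
    rmse: float
    mae: float
    ccc: float
    q2_loo: float
    rmse_loo: float
    mae_loo: float
    ccc_loo: float
    q2_kfold: float
    rmse_kfold: float
    k: int
    fold_seed: int
    fold_assignment: list[int]
    threshold_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.threshold_flags:
            self.threshold_flags = {
                "r2>0.6": self.r2 > THRESHOLDS["r2_min"],
                "q2>0.5": self.q2_loo > THRESHOLDS["q2_min"],
                "mae<0.6": self.mae < THRESHOLDS["mae_max"],
                "ccc>0.85": self.ccc > THRESHOLDS["ccc_min"],
            }


@dataclass
class YRandomizationReport:
    """Response-scrambling control: the real model must beat every shuffle."""

    n_reps: int
    original_r2: float
    original_q2: float
    shuffled_r2: list[float]
    shuffled_q2: list[float]
    seed: int

    @property
    def passed(self) -> bool:
        return all(r < self.original_r2 for r in self.shuffled_r2) and all(
            q < self.original_q2 for q in self.shuffled_q2
        )


def regression_metrics(
    y: np.ndarray, yhat: np.ndarray, p: int = 0
) -> tuple[float, float, float, float, float]:
    """(r2, r2_adjusted, rmse, mae, ccc) for observed vs predicted.

    r2 is 1 − SSres/SStot about mean(y); the adjusted form uses
    (n−1)/(n−p−1) and is NaN when n <= p+1.  CCC follows Lin:
    2·cov(y,ŷ) / (var(y) + var(ŷ) + (ȳ − ŷ̄)²) with 1/n moments.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero variance in y: r2 and ccc undefined")
    ssres = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ssres / sstot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else float("nan")
    rmse = float(np.sqrt(ssres / n))
    mae = float(np.mean(np.abs(y - yhat)))
    vy = float(np.var(y))
    vh = float(np.var(yhat))
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    ccc = 2.0 * cov / (vy + vh + (y.mean() - yhat.mean()) ** 2)
    return r2, r2_adj, rmse, mae, ccc


def loo_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions via the hat-matrix identity.

    For OLS the deleted residual is e_i / (1 − h_i); this equals n explicit
    refits exactly (property-tested against them).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n < p + 2:
        raise SingularDesignError(f"need n >= p + 2 for LOO, got n={n}, p={p}")
    fit = fit_ols(X, y)
    design = np.column_stack([np.ones(n), X])
    q, _ = np.linalg.qr(design)
    h = np.sum(q * q, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        bad = int(np.argmax(h))
        raise SingularDesignError(
            f"leave-one-out fit is rank-deficient when row {bad} is removed"
        )
    return y - fit.residuals / (1.0 - h)


def q2_loo(
    X: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float, np.ndarray]:
    """PRESS-based leave-one-out Q² with companion error statistics.

    Returns ``(q2, rmse_loo, mae_loo, ccc_loo, loo_predictions)``.
    """
    y = np.asarray(y, float).ravel()
    preds = loo_predictions(X, y)
    press = float(np.sum((y - preds) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero variance in y: Q2 undefined")
    q2 = 1.0 - press / sstot
    rmse = float(np.sqrt(press / len(y)))
    mae = float(np.mean(np.abs(y - preds)))
    _, _, _, _, ccc = regression_metrics(y, preds)
    return q2, rmse, mae, ccc, preds


def kfold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition of n rows into k near-equal folds (labels 0..k-1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    labels = np.array([i % k for i in range(n)])
    rng.shuffle(labels)
    return labels

def q2_kfold(
    X: np.ndarray, y: np.ndarray, k: int, seed: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """k-fold cross-validated Q² with pooled out-of-fold PRESS.

    Returns ``(q2_k, rmse_k, fold_assignment, pooled_predictions)``.
    k = n reduces exactly to leave-one-out.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    folds = kfold_assignment(n, k, seed)
    preds = np.empty(n)
    for f in range(k):
        test = folds == f
        fit = fit_ols(X[~test], y[~test])
        design = np.column_stack([np.ones(int(test.sum())), X[test]])
        preds[test] = design @ np.concatenate(
            [[fit.model.intercept], fit.model.coefficients]
        )
    press = float(np.sum((y - preds) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("zero variance in y: Q2 undefined")
    return 1.0 - press / sstot, float(np.sqrt(press / n)), folds, preds


def y_randomization(
    X: np.ndarray, y: np.ndarray, n_reps: int = 10, seed: int = 0
) -> YRandomizationReport:
    """Refit after seeded response permutations; the original must win every time."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    fit = fit_ols(X, y)
    r2, *_ = regression_metrics(y, fit.fitted_values, p=X.shape[1])
    q2, *_ = q2_loo(X, y)
    rng = np.random.default_rng(seed)
    shuffled_r2, shuffled_q2 = [], []
    for _ in range(n_reps):
        y_perm = rng.permutation(y)
        perm_fit = fit_ols(X, y_perm)
        pr2, *_ = regression_metrics(y_perm, perm_fit.fitted_values, p=X.shape[1])
        pq2, *_ = q2_loo(X, y_perm)
        shuffled_r2.append(pr2)
        shuffled_q2.append(pq2)
    return YRandomizationReport(
        n_reps=n_reps,
        original_r2=r2,
        original_q2=q2,
        shuffled_r2=shuffled_r2,
        shuffled_q2=shuffled_q2,
        seed=seed,
    )


def validation_report(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> ValidationReport:
    """Convenience: fit + full training/LOO/k-fold statistics in one report."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    fit = fit_ols(X, y)
    r2, r2a, rmse, mae, ccc = regression_metrics(y, fit.fitted_values, p=p)
    q2l, rmsel, mael, cccl, _ = q2_loo(X, y)
    q2k, rmsek, folds, _ = q2_kfold(X, y, k, seed)
    return ValidationReport(
        n=n, p=p, r2=r2, r2_adjusted=r2a, rmse=rmse, mae=mae, ccc=ccc,
        q2_loo=q2l, rmse_loo=rmsel, mae_loo=mael, ccc_loo=cccl,
        q2_kfold=q2k, rmse_kfold=rmsek, k=k, fold_seed=seed,
        fold_assignment=[int(f) for f in folds],
    )
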