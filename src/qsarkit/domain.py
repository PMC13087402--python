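"""Leverage-based applicability domain (Williams plot).

A compound lies inside a QSAR model's applicability domain when its
descriptor-space leverage h_i (the hat-matrix diagonal of the design,
intercept included) stays below the critical leverage h* = 3(p+1)/n and its
standardized residual stays within ±3σ.  The (h_i, standardized residual)
pairs are the coordinates of the Williams plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .linear import LinearModel, SingularDesignError, predict
from .tables import DescriptorTable

__all__ = [
    "ADReport",
    "leverages",
    "critical_leverage",
    "standardized_residuals",
    "williams_report",
]

SIGMA_BAND = 3.0


@dataclass
class ADReport:
    """Applicability-domain verdict per compound."""

    ids: list[str]
    leverages: np.ndarray
    h_star: float
    standardized_residuals: np.ndarray
    in_domain: np.ndarray
    sigma_band: float = SIGMA_BAND
    residual_variant: str = "simple"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "leverage": self.leverages,
                "std_residual": self.standardized_residuals,
                "in_domain": self.in_domain,
            }
        )

    def write_plot_data(self, path: str | Path) -> None:
        """Williams plot coordinates as CSV (id, leverage, std_residual, in_domain)."""
        self.to_frame().to_csv(Path(path), index=False)


def leverages(X: np.ndarray) -> np.ndarray:
    """Hat-matrix diagonal of the design [1 | X].

    Computed from the thin QR factorisation; satisfies 1/n <= h_i <= 1 and
    sum(h_i) = p + 1.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("rank-deficient design: leverages undefined")
    q, _ = np.linalg.qr(design)
    return np.sum(q * q, axis=1)


def critical_leverage(p: int, n: int) -> float:
    """Critical leverage h* = 3(p+1)/n for p descriptors and n compounds."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if p < 0:
        raise ValueError(f"p must be non-negative, got {p}")
    return 3.0 * (p + 1) / n


def standardized_residuals(
    residuals: np.ndarray,
    variant: str = "simple",
    leverage: np.ndarray | None = None,
) -> np.ndarray:
    """Residuals in σ units.

    ``simple`` divides by the sample (n−1) standard deviation of the raw
    residuals; ``studentized`` additionally scales each residual by
    sqrt(1 − h_i) (internally studentized, requires ``leverage``).
    """
    r = np.asarray(residuals, float).ravel()
    if len(r) < 2:
        raise ValueError("need at least 2 residuals")
    s = float(np.std(r, ddof=1))
    if s == 0:
        raise ValueError("zero residual spread: standardization undefined")
    if variant == "simple":
        return r / s
    if variant == "studentized":
        if leverage is None:
            raise ValueError("studentized variant requires leverages")
        h = np.asarray(leverage, float).ravel()
        return r / (s * np.sqrt(1.0 - h))
    raise ValueError(f"unknown variant {variant!r}")


def williams_report(
    X: np.ndarray,
    y: np.ndarray,
    model: LinearModel | None = None,
    ids: Sequence[str] | None = None,
    table: DescriptorTable | None = None,
    variant: str = "simple",
) -> ADReport:
    """Assemble the applicability-domain report.

    When ``model`` and ``table`` are given, residuals are y − model
    predictions on the table; otherwise an OLS fit on (X, y) supplies them.
    """
    from .linear import fit_ols  # deferred to keep module deps one-way

    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    h = leverages(X)
    h_star = critical_leverage(p, n)
    if model is not None and table is not None:
        resid = y - predict(model, table)
    else:
        resid = fit_ols(X, y).residuals
    sr = standardized_residuals(resid, variant=variant, leverage=h)
    in_domain = (h < h_star) & (np.abs(sr) <= SIGMA_BAND)
    id_list = list(ids) if ids is not None else [str(i) for i in range(n)]
    return ADReport(
        ids=id_list,
        leverages=h,
        h_star=h_star,
        standardized_residuals=sr,
        in_domain=in_domain,
        residual_variant=variant,
    )
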