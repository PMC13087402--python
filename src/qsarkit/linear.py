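"""Multiple linear regression QSAR engine.

The QSAR form is Y = m1*x1 + ... + mn*xn + b: a named response regressed on
a small ordered set of molecular descriptors, with the intercept always
present.  Fitting is ordinary least squares through a QR-class solver
(``numpy.linalg.lstsq``) with an explicit condition-number guard — a rank
deficient design is an error, never silently pseudo-inverted, because a
reported QSAR equation must be unique.

:func:`published_models` carries the two antioxidant equations of the
source study (radical scavenging %DPPH and SOD-mimic pIC50) verbatim as
fixtures for prediction and screening.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import DescriptorTable, TableFormatError, _json_dump, _json_load

__all__ = [
    "LinearModel",
    "FitResult",
    "SingularDesignError",
    "fit_ols",
    "predict",
    "published_models",
    "write_linear_model",
    "read_linear_model",
]

CONDITION_LIMIT = 1e10


class SingularDesignError(ValueError):
    """Design matrix is rank deficient or numerically singular."""


@dataclass(frozen=True)
class LinearModel:
    """A fitted (or published) linear QSAR equation."""

    name: str
    response_label: str
    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float

    def __init__(
        self,
        name: str,
        response_label: str,
        descriptor_names: Sequence[str],
        coefficients: Sequence[float],
        intercept: float,
    ):
        names = tuple(str(d) for d in descriptor_names)
        coefs = tuple(float(c) for c in coefficients)
        if len(names) != len(coefs):
            raise ValueError(
                f"{len(names)} descriptor names but {len(coefs)} coefficients"
            )
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names")
        if not all(math.isfinite(c) for c in coefs) or not math.isfinite(intercept):
            raise ValueError("coefficients and intercept must be finite")
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "response_label", str(response_label))
        object.__setattr__(self, "descriptor_names", names)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "intercept", float(intercept))

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def equation(self, decimals: int = 4) -> str:
        """Human-readable equation string, report-rounded."""
        parts = []
        for name, c in zip(self.descriptor_names, self.coefficients):
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(round(c, decimals))}({name})")
        b = self.intercept
        parts.append(f"{'-' if b < 0 else '+'} {abs(round(b, decimals))}")
        rhs = " ".join(parts).lstrip("+ ").strip()
        return f"{self.response_label} = {rhs}"


@dataclass(frozen=True)
class FitResult:
    """OLS fit output: the model plus training fits and residuals."""

    model: LinearModel
    fitted_values: np.ndarray
    residuals: np.ndarray
    n: int
    p: int


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    name: str = "ols",
    response_label: str = "y",
    allow_exact_fit: bool = False,
) -> FitResult:
    """Least-squares fit of y on X with intercept.

    Raises :class:`SingularDesignError` on rank deficiency or a condition
    number above 1e10, and an under-determined error when n <= p (unless
    ``allow_exact_fit`` permits saturated demos).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} entries")
    if n <= p and not allow_exact_fit:
        raise SingularDesignError(f"under-determined: n={n} <= p={p}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dep = _dependent_columns(design, names)
        raise SingularDesignError(f"rank-deficient design; dependent columns: {dep}")
    if np.linalg.cond(design) > CONDITION_LIMIT:
        raise SingularDesignError(
            f"design condition number exceeds {CONDITION_LIMIT:g}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    names = list(names) if names is not None else [f"x{j + 1}" for j in range(p)]
    model = LinearModel(name, response_label, names, beta[1:], beta[0])
    return FitResult(model=model, fitted_values=fitted, residuals=y - fitted, n=n, p=p)


def _dependent_columns(design: np.ndarray, names: Sequence[str] | None) -> list[str]:
    labels = ["<intercept>"] + (
        list(names) if names is not None else [f"x{j + 1}" for j in range(design.shape[1] - 1)]
    )
    dep = []
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        trial = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept = trial
        else:
            dep.append(labels[j])
    return dep


def predict(model: LinearModel, table: DescriptorTable) -> np.ndarray:
    """Apply a linear model to a descriptor table, in the model's column order.

    Extra table columns are ignored; a missing descriptor is an error naming
    the absent column.
    """
    cols = []
    for name in model.descriptor_names:
        try:
            cols.append(table.column(name))
        except KeyError:
            raise KeyError(
                f"descriptor {name!r} required by model {model.name!r} "
                f"is missing from the table"
            ) from None
    X = np.column_stack(cols) if cols else np.empty((table.n_compounds, 0))
    return model.intercept + (X @ np.asarray(model.coefficients) if cols else 0.0)


def published_models() -> dict[str, LinearModel]:
    """The two published antioxidant QSAR equations, coefficients verbatim.

    - ``dpph``: %DPPH radical scavenging on ATS5s, GATS1e, Mor04p, Mor24u.
    - ``sod``: SOD-mimic pIC50 on R1v, AATS8p, B08[C–O], D211.
    """
    dpph = LinearModel(
        name="dpph",
        response_label="%DPPH",
        descriptor_names=("ATS5s", "GATS1e", "Mor04p", "Mor24u"),
        coefficients=(0.0685, -74.5372, -6.0133, -12.0745),
        intercept=20.4924,
    )
    sod = LinearModel(
        name="sod",
        response_label="pIC50",
        descriptor_names=("R1v", "AATS8p", "B08[C–O]", "D211"),
        coefficients=(7.8664, -2.2827, -0.1794, 22.3828),
        intercept=-3.3978,
    )
    return {"dpph": dpph, "sod": sod}


# ---------------------------------------------------------------------------
# JSON serialization (lossless: floats stored via repr round-trip)


def write_linear_model(model: LinearModel, path: str | Path) -> None:
    _json_dump(
        {
            "type": "linear_model",
            "name": model.name,
            "response_label": model.response_label,
            "descriptor_names": list(model.descriptor_names),
            "coefficients": list(model.coefficients),
            "intercept": model.intercept,
        },
        path,
    )


def read_linear_model(path: str | Path) -> LinearModel:
    data = _json_load(path)
    try:
        return LinearModel(
            name=data["name"],
            response_label=data["response_label"],
            descriptor_names=data["descriptor_names"],
            coefficients=data["coefficients"],
            intercept=data["intercept"],
        )
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"{path}: malformed linear model ({exc})") from exc
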