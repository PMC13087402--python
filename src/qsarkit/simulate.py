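"""Synthetic study generators.

Small-n / wide-p QSAR practice is hard to test on real descriptor matrices
(they are rarely redistributable), so this module generates tables with the
statistical structure the pipeline assumes: a handful of informative
descriptors with known linear coefficients buried in a correlated nuisance
block, axis-aligned two-level class rules with margins, and two-fold
dilution series with a known IC50.  Every generator is a pure function of
its scenario plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import DilutionSeries
from .tables import DescriptorTable

__all__ = [
    "RegressionScenario",
    "ClassificationScenario",
    "gen_regression",
    "gen_classification",
    "gen_assay",
]


@dataclass(frozen=True)
class RegressionScenario:
    """Planted-linear-signal descriptor table.

    Defaults emulate the study regime this toolkit targets: ~11 compounds,
    a wide descriptor block of which 4 carry signal, strong intercorrelation
    (rho = 0.85) inside the nuisance block so the |r| <= 0.9 independence
    check is exercised, and near-noiseless response (small-n QSAR models in
    this regime report training R² above 0.99).
    """

    n_compounds: int = 11
    n_descriptors: int = 40
    informative: tuple[str, ...] = ("ATS5s", "GATS1e", "Mor04p", "Mor24u")
    true_coefficients: tuple[float, ...] = (0.0685, -74.5372, -6.0133, -12.0745)
    true_intercept: float = 20.4924
    noise_sd: float = 0.0
    collinearity_rho: float = 0.85
    n_binary: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.informative) != len(self.true_coefficients):
            raise ValueError("informative names and coefficients must align")
        if self.n_descriptors < len(self.informative):
            raise ValueError("n_descriptors smaller than informative count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.collinearity_rho) < 1:
            raise ValueError("|collinearity_rho| must be < 1")


def gen_regression(
    scenario: RegressionScenario,
) -> tuple[DescriptorTable, np.ndarray, dict]:
    """Generate (table, response, truth record).

    Informative columns are independent unit normals; nuisance columns form
    an equicorrelated block (pairwise correlation rho) plus optional
    Bernoulli columns mimicking binary atom-pair descriptors.  The response
    is the exact planted linear combination plus Gaussian noise.
    """
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_compounds, scenario.n_descriptors
    k = len(scenario.informative)
    informative = rng.standard_normal((n, k))
    n_noise = p - k
    names = list(scenario.informative)
    blocks = [informative]
    if n_noise > 0:
        n_bin = min(scenario.n_binary, n_noise)
        n_corr = n_noise - n_bin
        if n_corr > 0:
            rho = scenario.collinearity_rho
            shared = rng.standard_normal((n, 1))
            unique = rng.standard_normal((n, n_corr))
            block = np.sqrt(abs(rho)) * np.sign(rho) * shared + np.sqrt(1 - abs(rho)) * unique
            blocks.append(block)
            names += [f"NZ{j + 1}" for j in range(n_corr)]
        if n_bin > 0:
            blocks.append(rng.integers(0, 2, size=(n, n_bin)).astype(float))
            names += [f"BIN{j + 1}" for j in range(n_bin)]
    X = np.column_stack(blocks)
    beta = np.asarray(scenario.true_coefficients)
    y = scenario.true_intercept + informative @ beta
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=n)
    ids = [f"C{i + 1}" for i in range(n)]
    table = DescriptorTable(ids, names, X)
    truth = {
        "informative": list(scenario.informative),
        "coefficients": [float(b) for b in beta],
        "intercept": float(scenario.true_intercept),
        "noise_sd": float(scenario.noise_sd),
        "seed": int(scenario.seed),
    }
    return table, y, truth


@dataclass(frozen=True)
class ClassificationScenario:
    """Two-level threshold rule mirroring a root + one internal split.

    Class is 'active' when descriptor1 <= t1, or when descriptor1 > t1 and
    descriptor2 > t2; otherwise 'inactive'.  Points keep at least ``margin``
    distance from both thresholds.  The default 7:4 balance at n = 11
    reproduces the shape of the study panel this toolkit was written
    around.
    """

    descriptor1: str = "X4sol"
    t1: float = 7.564
    descriptor2: str = "VR2_Dzi"
    t2: float = 11.729
    n_compounds: int = 11
    n_active: int = 7
    margin: float = 0.5
    spread: float = 2.0
    n_nuisance: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not 0 <= self.n_active <= self.n_compounds:
            raise ValueError("n_active out of range")
        if self.spread <= self.margin:
            raise ValueError("spread must exceed margin")


def gen_classification(
    scenario: ClassificationScenario,
) -> tuple[DescriptorTable, list[str]]:
    """Generate (table, class labels) exactly following the planted rule.

    Actives are drawn alternately from the shallow region (d1 below t1) and
    the deep region (d1 above t1, d2 above t2); inactives from d1 above t1
    with d2 below t2.  All coordinates stay ``margin`` away from thresholds.
    """
    rng = np.random.default_rng(scenario.seed)
    s = scenario

    def away_below(t: float) -> float:
        return t - s.margin - rng.uniform(0, s.spread - s.margin)

    def away_above(t: float) -> float:
        return t + s.margin + rng.uniform(0, s.spread - s.margin)

    rows, labels = [], []
    for i in range(s.n_compounds):
        active = i < s.n_active
        if active:
            if i % 2 == 0:
                # shallow-active region: class fixed by d1 alone, but d2 also
                # keeps its margin so every axis-aligned boundary stays clear
                d2_side = away_above(s.t2) if rng.random() < 0.5 else away_below(s.t2)
                d1, d2 = away_below(s.t1), d2_side
            else:
                d1, d2 = away_above(s.t1), away_above(s.t2)
        else:
            d1, d2 = away_above(s.t1), away_below(s.t2)
        rows.append([d1, d2] + list(rng.standard_normal(s.n_nuisance)))
        labels.append("active" if active else "inactive")
    order = rng.permutation(s.n_compounds)
    rows = [rows[i] for i in order]
    labels = [labels[i] for i in order]
    names = [s.descriptor1, s.descriptor2] + [f"NZ{j + 1}" for j in range(s.n_nuisance)]
    ids = [f"C{i + 1}" for i in range(s.n_compounds)]
    return DescriptorTable(ids, names, np.asarray(rows)), labels


def gen_assay(
    true_ic50: float,
    top_conc: float = 300.0,
    n_dilutions: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Two-fold dilution series through a saturating response curve.

    Responses follow the hyperbolic curve 100*c/(c + IC50), which passes
    through 50% exactly at the true IC50, plus seeded Gaussian noise.
    """
    if not true_ic50 > 0:
        raise ValueError("true_ic50 must be positive")
    if not top_conc > 0:
        raise ValueError("top_conc must be positive")
    if n_dilutions < 2:
        raise ValueError("need at least 2 dilutions")
    rng = np.random.default_rng(seed)
    conc = top_conc / (2.0 ** np.arange(n_dilutions))
    resp = 100.0 * conc / (conc + true_ic50)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=n_dilutions)
    return DilutionSeries(conc.tolist(), resp.tolist())
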