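"""Reduction of raw assay readings to modelling endpoints.

Covers the standard antioxidant-assay arithmetic: percent inhibition from
absorbances, IC50 from a 2-fold dilution series, the pIC50 transform, and
MIC unit conversion from µg/ml to µM.  None of this fits dose-response
curves; a two-fold dilution design with a single 50% crossing is reduced by
log2-linear interpolation, which is the natural interpolant for that design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables import ActivityRecord

__all__ = [
    "AssayReading",
    "DilutionSeries",
    "IC50Estimate",
    "percent_inhibition",
    "ic50_from_series",
    "pic50_from_micromolar",
    "mic_to_micromolar",
    "classify_antimicrobial",
]


@dataclass(frozen=True)
class AssayReading:
    """One spectrophotometric reading pair (sample vs control absorbance)."""

    abs_sample: float
    abs_control: float

    def __post_init__(self) -> None:
        if not self.abs_control > 0:
            raise ValueError(f"control absorbance must be > 0, got {self.abs_control}")
        if self.abs_sample < 0:
            raise ValueError(f"sample absorbance must be >= 0, got {self.abs_sample}")


@dataclass(frozen=True)
class DilutionSeries:
    """Responses (% inhibition) measured along 2-fold descending concentrations."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __init__(self, concentrations: Sequence[float], responses: Sequence[float]):
        conc = tuple(float(c) for c in concentrations)
        resp = tuple(float(r) for r in responses)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses must have equal length")
        if len(conc) < 2:
            raise ValueError("a dilution series needs at least 2 points")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be strictly positive")
        if any(c_hi <= c_lo for c_hi, c_lo in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)


@dataclass(frozen=True)
class IC50Estimate:
    """IC50 in the series' concentration unit.

    ``value`` is None when no concentration reached 50% inhibition (the
    endpoint is then reported as undetermined, matching assay practice).
    ``censored`` marks the case where even the lowest tested concentration
    inhibited >= 50%, so the estimate is only an upper bound.
    """

    value: float | None
    censored: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


def percent_inhibition(reading: AssayReading) -> tuple[float, bool]:
    """Percent inhibition ``(1 - Abs_sample/Abs_control) * 100``.

    Returns ``(percent, pro_oxidant_flag)``; a negative percent (sample
    absorbance above the control) is returned as measured with the flag set,
    never clipped.
    """
    pct = (1.0 - reading.abs_sample / reading.abs_control) * 100.0
    return pct, pct < 0


def ic50_from_series(series: DilutionSeries) -> IC50Estimate:
    """Half-maximal inhibitory concentration from a 2-fold dilution series.

    * max response < 50  -> undetermined (``value is None``);
    * some response == 50 exactly -> that concentration;
    * otherwise linear interpolation of response against log2(concentration)
      between the lowest concentration whose response >= 50 and the next
      dilution below it;
    * every response >= 50 -> the lowest concentration, censored ("<=").
    """
    conc = series.concentrations
    resp = series.responses
    if max(resp) < 50.0:
        return IC50Estimate(None)
    for c, r in zip(conc, resp):
        if r == 50.0:
            return IC50Estimate(c)
    # lowest concentration (last index, descending order) with response >= 50
    idx = max(i for i, r in enumerate(resp) if r >= 50.0)
    if idx == len(conc) - 1:
        return IC50Estimate(conc[idx], censored=True)
    hi_c, hi_r = conc[idx], resp[idx]
    lo_c, lo_r = conc[idx + 1], resp[idx + 1]
    frac = (50.0 - lo_r) / (hi_r - lo_r)
    log2_ic50 = math.log2(lo_c) + frac * (math.log2(hi_c) - math.log2(lo_c))
    return IC50Estimate(2.0 ** log2_ic50)


def pic50_from_micromolar(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in molar) from an IC50 given in µM.

    With the IC50 in µM this is ``6 - log10(IC50)``; reports round to 3
    decimals.
    """
    if not (ic50_um > 0 and math.isfinite(ic50_um)):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_um}")
    return 6.0 - math.log10(ic50_um)


def mic_to_micromolar(mic_ug_ml: float, mw: float) -> float:
    """Convert a MIC from µg/ml to µM using the molecular weight (g/mol)."""
    if not mic_ug_ml > 0:
        raise ValueError(f"MIC must be positive, got {mic_ug_ml}")
    if not mw > 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return mic_ug_ml / mw * 1000.0


def classify_antimicrobial(record: ActivityRecord) -> str:
    """'active' iff the compound has at least one MIC record, else 'inactive'."""
    return record.antimicrobial_class
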