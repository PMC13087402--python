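"""Published study panel of 8-aminoquinoline sulfonamide hybrids.

The toolkit ships the printed experimental endpoints of the eleven
synthesized hybrids (compounds 3-13) as a worked-example dataset: %DPPH
radical scavenging at 300 µg/ml, SOD-mimic IC50 (µM), molecular weights,
and the per-organism minimum inhibitory concentrations.  The full
descriptor matrices behind the published equations live only in
supplementary material and are not redistributed here; the panel carries
what the published tables print, which is sufficient for unit conversions,
activity classification and the worked classification example.
"""

from __future__ import annotations

from .tables import ActivityRecord, ActivityTable, MICRecord

__all__ = [
    "study_panel",
    "PREDICTED_ACTIVE",
    "MOLECULAR_WEIGHTS",
]

# Dragon-calculated molecular weights (g/mol) for compounds 3-13.
MOLECULAR_WEIGHTS: dict[str, float] = {
    "3": 302.35, "4": 318.80, "5": 363.25, "6": 352.36, "7": 326.40,
    "8": 309.37, "9": 329.36, "10": 329.36, "11": 340.48, "12": 334.42,
    "13": 362.46,
}

# (%DPPH at 300 µg/ml, SOD IC50 in µM or None when activity stayed < 50%)
_ANTIOXIDANT: dict[str, tuple[float, float | None]] = {
    "3": (10.09, 153.56),
    "4": (9.26, None),
    "5": (7.74, 212.58),
    "6": (12.06, 247.39),
    "7": (9.79, 250.37),
    "8": (12.53, 96.07),
    "9": (36.49, 254.58),
    "10": (19.06, 448.75),
    "11": (22.43, 530.93),
    "12": (13.88, 83.34),
    "13": (17.33, 600.81),
}

# MIC in µg/ml per organism; negative sign convention not used — a "<=" bound
# is stored censored.  Compounds 7, 9, 11 and 13 showed no inhibition at the
# highest tested concentration and have empty maps.
_LE = True  # marker for censored "<=" bounds
_MIC: dict[str, dict[str, tuple[float, bool]]] = {
    "3": {
        "B. cereus": (128, False),
        "S. aureus ATCC 29213": (64, False),
        "S. aureus ATCC 25923": (64, False),
        "M. luteus ATCC 10240": (64, False),
        "MRSA JCSC 4788": (64, False),
        "MRSA N315": (8, False),
        "B. subtilis ATCC 6633": (4, _LE),
        "MRSA JCSC 3063": (4, _LE),
    },
    "4": {
        "S. aureus ATCC 29213": (64, False),
        "S. epidermidis ATCC 12228": (64, False),
        "P. shigelloides": (16, False),
        "L. monocytogenes": (16, False),
        "S. aureus ATCC 25923": (4, _LE),
        "M. luteus ATCC 10240": (4, _LE),
        "B. subtilis ATCC 6633": (4, _LE),
        "B. cereus": (4, _LE),
        "MRSA JCSC 3063": (4, _LE),
        "MRSA N315": (4, _LE),
        "MRSA JCSC 4788": (4, _LE),
    },
    "5": {
        "MRSA N315": (8, False),
        "B. subtilis ATCC 6633": (4, _LE),
        "MRSA JCSC 3063": (4, _LE),
    },
    "6": {
        "S. aureus ATCC 25923": (4, _LE),
        "B. subtilis ATCC 6633": (4, _LE),
        "B. cereus": (4, _LE),
        "P. shigelloides": (4, _LE),
        "L. monocytogenes": (4, _LE),
        "MRSA JCSC 3063": (4, _LE),
        "MRSA N315": (4, _LE),
        "MRSA JCSC 4788": (4, _LE),
    },
    "7": {},
    "8": {
        "A. hydrophila": (128, False),
        "S. aureus ATCC 25923": (4, _LE),
        "B. subtilis ATCC 6633": (4, _LE),
        "B. cereus": (4, _LE),
        "MRSA JCSC 3063": (4, _LE),
        "MRSA N315": (4, _LE),
    },
    "9": {},
    "10": {"B. cereus": (128, False)},
    "11": {},
    "12": {
        "E. coli ATCC 25922": (256, False),
        "S. typhimurium ATCC 13311": (256, False),
        "P. stutzeri ATCC 17587": (256, False),
        "S. enteritidis": (256, False),
        "M. morganii": (256, False),
        "A. hydrophila": (256, False),
        "C. freundii": (256, False),
    },
    "13": {},
}

# Training-set predictions of the published classification tree: the rule
# routes the four halogenated hybrids plus the nitrile one through the
# shallow active leaf, sends 10 and 12 through the deep active leaf, and
# misroutes the inactive acetyl compound 7 there as well.
PREDICTED_ACTIVE: frozenset[str] = frozenset(
    {"3", "4", "5", "6", "7", "8", "10", "12"}
)


def study_panel() -> ActivityTable:
    """The eleven-compound panel as an :class:`ActivityTable`."""
    records = []
    for cid, (dpph, sod) in _ANTIOXIDANT.items():
        records.append(
            ActivityRecord(
                compound_id=cid,
                mw=MOLECULAR_WEIGHTS[cid],
                dpph_percent=dpph,
                sod_ic50=sod,
                mic_records={
                    org: MICRecord(val, censored)
                    for org, (val, censored) in _MIC[cid].items()
                },
            )
        )
    return ActivityTable(records)
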