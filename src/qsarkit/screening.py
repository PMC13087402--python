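"""Model-guided screening of designed candidate compounds.

Applies stored regression equations and the classification tree to a
candidate descriptor table, ranks candidates per endpoint, and flags which
candidates are predicted to improve on their experimental prototypes (the
workflow behind screening a designed-analog series before synthesis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .linear import LinearModel, predict
from .tables import ActivityTable, DescriptorTable
from .tree import TreeModel, apply_tree

__all__ = ["CandidateResult", "ScreeningReport", "screen", "top_k"]

log = logging.getLogger(__name__)


@dataclass
class CandidateResult:
    candidate_id: str
    predictions: dict[str, float]          # endpoint -> predicted value
    predicted_class: str | None
    prototype_id: str | None
    prototype_values: dict[str, float]     # endpoint -> experimental value
    improvement: dict[str, bool]           # endpoint -> predicted > prototype
    plausibility_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ScreeningReport:
    """Per-candidate predictions, improvement flags and per-endpoint ranks."""

    candidates: list[CandidateResult]
    ranks: dict[str, list[str]]  # endpoint -> candidate ids best-first

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row: dict[str, object] = {
                "candidate_id": c.candidate_id,
                "predicted_class": c.predicted_class,
                "prototype_id": c.prototype_id,
            }
            for ep, val in c.predictions.items():
                row[f"pred_{ep}"] = val
                row[f"rank_{ep}"] = self.ranks[ep].index(c.candidate_id) + 1
                if ep in c.improvement:
                    row[f"improved_{ep}"] = c.improvement[ep]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.candidates:
            if c.predicted_class is not None:
                counts[c.predicted_class] = counts.get(c.predicted_class, 0) + 1
        return counts


_ENDPOINT_BY_MODEL = {"dpph": "dpph_percent", "sod": "sod_pic50"}


def screen(
    candidates: DescriptorTable | None,
    models: Mapping[str, LinearModel],
    tree: TreeModel | None = None,
    prototypes: ActivityTable | None = None,
    prototype_map: Mapping[str, str] | None = None,
) -> ScreeningReport:
    """Predict every endpoint for every candidate and rank the results.

    ``prototype_map`` maps candidate id -> prototype compound id; a missing
    mapping leaves the candidate without improvement flags (warned, not
    fatal).  Ranking is by predicted value descending, ties broken by
    candidate id.  %DPPH predictions outside [0, 100] are reported as-is
    with a plausibility flag.
    """
    if candidates is None or candidates.n_compounds == 0:
        return ScreeningReport(candidates=[], ranks={m: [] for m in models})
    preds = {name: predict(model, candidates) for name, model in models.items()}
    classes = apply_tree(tree, candidates) if tree is not None else None
    prototype_map = dict(prototype_map or {})

    results: list[CandidateResult] = []
    for i, cid in enumerate(candidates.compound_ids):
        proto_id = prototype_map.get(cid)
        proto_vals: dict[str, float] = {}
        improvement: dict[str, bool] = {}
        plaus: dict[str, bool] = {}
        if proto_id is None and prototype_map:
            log.warning("candidate %s has no prototype mapping", cid)
        for mname in models:
            endpoint = _ENDPOINT_BY_MODEL.get(mname, mname)
            val = float(preds[mname][i])
            if mname == "dpph":
                plaus[mname] = 0.0 <= val <= 100.0
            if proto_id is not None and prototypes is not None and proto_id in prototypes:
                proto = prototypes[proto_id]
                exp = prototypes.endpoint(proto, endpoint) if endpoint in (
                    "dpph_percent", "sod_ic50", "sod_pic50"
                ) else None
                if exp is not None:
                    proto_vals[mname] = float(exp)
                    improvement[mname] = val > float(exp)
        results.append(
            CandidateResult(
                candidate_id=cid,
                predictions={m: float(preds[m][i]) for m in models},
                predicted_class=classes[i] if classes is not None else None,
                prototype_id=proto_id,
                prototype_values=proto_vals,
                improvement=improvement,
                plausibility_flags=plaus,
            )
        )
    ranks = {
        mname: [
            cid
            for _, cid in sorted(
                zip(-np.asarray(preds[mname], float), candidates.compound_ids),
                key=lambda t: (t[0], t[1]),
            )
        ]
        for mname in models
    }
    return ScreeningReport(candidates=results, ranks=ranks)


def top_k(report: ScreeningReport, endpoint: str, k: int) -> list[CandidateResult]:
    """First k candidates by rank for one endpoint (all of them if k > n)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if endpoint not in report.ranks:
        raise KeyError(f"unknown endpoint {endpoint!r}")
    order = report.ranks[endpoint]
    if k > len(order):
        log.warning("k=%d exceeds candidate count %d; returning all", k, len(order))
        k = len(order)
    by_id = {c.candidate_id: c for c in report.candidates}
    return [by_id[cid] for cid in order[:k]]
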