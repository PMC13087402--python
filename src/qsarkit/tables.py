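"""Core data containers and their CSV/JSON persistence.

A QSAR study revolves around two flat tables: a *descriptor table*
(compounds x named numeric molecular descriptors) and an *activity table*
(per-compound experimental endpoints — %DPPH inhibition, SOD IC50 in µM,
minimum inhibitory concentrations per organism, molecular weight).  Both are
kept as thin, validated wrappers over :class:`pandas.DataFrame` so that
column order, compound identity and finiteness are guaranteed invariants
rather than conventions.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DescriptorTable",
    "ActivityRecord",
    "ActivityTable",
    "MICRecord",
    "PipelineConfig",
    "TableFormatError",
    "JoinError",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_activity_table",
    "write_activity_table",
    "join_tables",
    "DESCRIPTOR_ALIASES",
]

# The B08[C-O] atom-pair flag is printed with an en-dash in some sources and
# an ASCII hyphen in others; both spellings resolve to the same column.
DESCRIPTOR_ALIASES: dict[str, str] = {
    "B08[C-O]": "B08[C–O]",
}


class TableFormatError(ValueError):
    """Raised when a table file or in-memory table violates format invariants."""


class JoinError(ValueError):
    """Raised when descriptor and activity tables cannot be joined."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TableFormatError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class DescriptorTable:
    """Compounds x named numeric molecular descriptors.

    Parameters
    ----------
    compound_ids : sequence of str
        Unique compound labels; row order is significant.
    descriptor_names : sequence of str
        Unique descriptor symbols (e.g. ``ATS5s``, ``GATS1e``, ``X4sol``);
        column order is significant and survives read/write round-trips.
    values : (n_compounds, n_descriptors) array
        Finite descriptor values (descriptors are unitless).
    """

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray

    def __init__(
        self,
        compound_ids: Iterable[str],
        descriptor_names: Iterable[str],
        values: np.ndarray | Sequence[Sequence[float]],
    ):
        ids = tuple(str(c) for c in compound_ids)
        names = tuple(str(d) for d in descriptor_names)
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 2:
            raise TableFormatError("values must be a 2-D matrix")
        if vals.shape != (len(ids), len(names)):
            raise TableFormatError(
                f"shape mismatch: {vals.shape} vs ({len(ids)}, {len(names)})"
            )
        if len(ids) == 0 or len(names) == 0:
            raise TableFormatError("empty descriptor table")
        _check_unique(ids, "compound id")
        _check_unique(names, "descriptor name")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise TableFormatError(
                f"non-finite value at compound {ids[i]!r}, descriptor {names[j]!r}"
            )
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "compound_ids", ids)
        object.__setattr__(self, "descriptor_names", names)
        object.__setattr__(self, "values", vals)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def resolve(self, name: str) -> str:
        """Resolve a descriptor name through the alias map; raise KeyError if absent."""
        if name in self.descriptor_names:
            return name
        alias = DESCRIPTOR_ALIASES.get(name)
        if alias is not None and alias in self.descriptor_names:
            return alias
        # reverse direction: stored ASCII, asked with typographic dash
        for ascii_name, fancy in DESCRIPTOR_ALIASES.items():
            if name == fancy and ascii_name in self.descriptor_names:
                return ascii_name
        raise KeyError(f"descriptor {name!r} not present in table")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(self.resolve(name))]

    def select_columns(self, names: Sequence[str]) -> "DescriptorTable":
        resolved = [self.resolve(n) for n in names]
        idx = [self.descriptor_names.index(n) for n in resolved]
        return DescriptorTable(self.compound_ids, resolved, self.values[:, idx])

    def select_rows(self, ids: Sequence[str]) -> "DescriptorTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        idx = [pos[c] for c in ids]
        return DescriptorTable(ids, self.descriptor_names, self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.values),
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=list(self.descriptor_names),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorTable":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(dtype=float),
        )

    def equals(self, other: "DescriptorTable") -> bool:
        return (
            self.compound_ids == other.compound_ids
            and self.descriptor_names == other.descriptor_names
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class MICRecord:
    """A minimum inhibitory concentration against one organism, µg/ml.

    ``censored`` marks "<=" bounds (the assay's lowest tested concentration
    still inhibited growth, so the true MIC is at or below ``value``).
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError(f"MIC must be positive and finite, got {self.value}")


@dataclass(frozen=True)
class ActivityRecord:
    """Experimental endpoints for one compound."""

    compound_id: str
    mw: float
    dpph_percent: float | None = None
    sod_ic50: float | None = None  # µM
    mic_records: Mapping[str, MICRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.mw > 0 and math.isfinite(self.mw)):
            raise ValueError(f"molecular weight must be positive, got {self.mw}")
        if self.sod_ic50 is not None and not self.sod_ic50 > 0:
            raise ValueError(f"SOD IC50 must be positive, got {self.sod_ic50}")
        object.__setattr__(self, "mic_records", dict(self.mic_records))

    @property
    def sod_pic50(self) -> float | None:
        """pIC50 = -log10(IC50 in molar); derived from the µM IC50."""
        if self.sod_ic50 is None:
            return None
        return 6.0 - math.log10(self.sod_ic50)

    @property
    def antimicrobial_class(self) -> str:
        """'active' iff at least one MIC record exists, else 'inactive'."""
        return "active" if self.mic_records else "inactive"


class ActivityTable:
    """Ordered collection of :class:`ActivityRecord` keyed by compound id."""

    def __init__(self, records: Iterable[ActivityRecord]):
        recs = list(records)
        _check_unique([r.compound_id for r in recs], "compound id")
        self._records: dict[str, ActivityRecord] = {r.compound_id: r for r in recs}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._records

    def __getitem__(self, compound_id: str) -> ActivityRecord:
        return self._records[compound_id]

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(self._records)

    def endpoint(self, record: ActivityRecord, name: str) -> float | None:
        if name == "dpph_percent":
            return record.dpph_percent
        if name == "sod_ic50":
            return record.sod_ic50
        if name == "sod_pic50":
            return record.sod_pic50
        raise KeyError(f"unknown endpoint {name!r}")


# ---------------------------------------------------------------------------
# CSV IO


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a descriptor CSV (first column = compound id, header row = names).

    The dialect is strict: comma separated, dot decimal, header mandatory,
    every cell numeric.  Errors carry the offending row/column address.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise TableFormatError(f"{path}: empty descriptor table")
    _check_unique(header[1:], "descriptor name")  # pandas would mangle dupes
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise TableFormatError(f"{path}: empty descriptor table")
    _check_unique([str(i) for i in frame.index], "compound id")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j].strip()
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {frame.index[i]!r}, "
                    f"column {frame.columns[j]!r}"
                ) from None
    return DescriptorTable(
        [str(i) for i in frame.index], [str(c) for c in frame.columns], values
    )


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a descriptor table as CSV with full double precision."""
    frame = table.to_frame()
    frame.to_csv(Path(path), float_format="%.17g")


_MIC_PREFIX = "mic:"


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read an activity CSV.

    Columns: ``compound_id, dpph_percent, sod_ic50_uM, mw`` then one
    ``mic:<organism>`` column per organism.  Empty MIC cell means no
    inhibition observed; a ``<=`` prefix marks a censored bound.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"compound_id", "mw"}
    missing = required - set(frame.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    organisms = [c[len(_MIC_PREFIX):] for c in frame.columns if c.startswith(_MIC_PREFIX)]
    records = []
    for _, row in frame.iterrows():
        mic: dict[str, MICRecord] = {}
        for org in organisms:
            cell = str(row[_MIC_PREFIX + org]).strip()
            if not cell:
                continue
            censored = cell.startswith("<=")
            mic[org] = MICRecord(float(cell[2:] if censored else cell), censored)

        def _opt(col: str) -> float | None:
            if col not in frame.columns:
                return None
            cell = str(row[col]).strip()
            return float(cell) if cell else None

        records.append(
            ActivityRecord(
                compound_id=str(row["compound_id"]),
                mw=float(row["mw"]),
                dpph_percent=_opt("dpph_percent"),
                sod_ic50=_opt("sod_ic50_uM"),
                mic_records=mic,
            )
        )
    return ActivityTable(records)


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    organisms = sorted({org for rec in table for org in rec.mic_records})
    rows = []
    for rec in table:
        row: dict[str, object] = {
            "compound_id": rec.compound_id,
            "dpph_percent": "" if rec.dpph_percent is None else repr(rec.dpph_percent),
            "sod_ic50_uM": "" if rec.sod_ic50 is None else repr(rec.sod_ic50),
            "mw": repr(rec.mw),
        }
        for org in organisms:
            mic = rec.mic_records.get(org)
            if mic is None:
                row[_MIC_PREFIX + org] = ""
            else:
                row[_MIC_PREFIX + org] = ("<=" if mic.censored else "") + repr(mic.value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Joining


def join_tables(
    desc: DescriptorTable, act: ActivityTable, response: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build a modelling dataset for one endpoint.

    Rows are restricted to compounds that have a defined value for
    ``response`` (``dpph_percent``, ``sod_ic50`` or ``sod_pic50``) —
    compounds lacking the endpoint are dropped, never coerced to zero.
    Row order of the descriptor table is preserved.

    Returns ``(X, y, ids)``.
    """
    overlap = [c for c in desc.compound_ids if c in act]
    if not overlap:
        raise JoinError("no compound ids shared between descriptor and activity tables")
    ids: list[str] = []
    ys: list[float] = []
    for cid in overlap:
        val = act.endpoint(act[cid], response)
        if val is not None:
            ids.append(cid)
            ys.append(float(val))
    if not ids:
        raise JoinError(f"endpoint {response!r} undefined for every shared compound")
    sub = desc.select_rows(ids)
    return np.asarray(sub.values), np.asarray(ys), ids


# ---------------------------------------------------------------------------
# Pipeline configuration

DEFAULT_SEED = 20260417


@dataclass
class PipelineConfig:
    """Run-wide settings with the package defaults.

    seed
        Root seed recorded in every report.
    cv_folds
        k for k-fold cross-validation (default 5).
    y_randomization_reps
        Number of response permutations (default 10).
    alpha_enter / alpha_remove
        Stepwise entry/removal p-value thresholds (0.05 / 0.10).
    intercorrelation_cutoff
        |r| bound for descriptor independence (0.9).
    tree_min_leaf
        Minimum training samples per tree leaf (2).
    rounding
        Decimals for displayed coefficients in reports.
    """

    seed: int = DEFAULT_SEED
    cv_folds: int = 5
    y_randomization_reps: int = 10
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    intercorrelation_cutoff: float = 0.9
    tree_min_leaf: int = 2
    rounding: int = 4

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.y_randomization_reps < 0:
            raise ValueError("y_randomization_reps must be >= 0")
        if not (0 < self.alpha_enter <= self.alpha_remove < 1):
            raise ValueError("need 0 < alpha_enter <= alpha_remove < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _json_dump(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def _json_load(path: str | Path) -> dict:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TableFormatError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: expected a JSON object")
    return data
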