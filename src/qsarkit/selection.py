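"""Descriptor feature selection for small-n / wide-p tables.

Three stages mirror standard QSAR practice: (1) drop constant and duplicate
descriptor columns, (2) pick an informative subset either by classical
stepwise multiple linear regression (forward entry / backward removal on
partial-F p-values) or by correlation-based feature subset (CFS) merit with
best-first search, (3) verify the survivors' pairwise independence against
an |r| cutoff (0.9 by default).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables import DescriptorTable

__all__ = [
    "SelectionResult",
    "SelectionError",
    "constant_redundant_filter",
    "stepwise_select",
    "cfs_bestfirst",
    "cfs_merit",
    "intercorrelation_check",
]


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``selected`` holds column indices into the input matrix (in entry order);
    ``selected_names`` the corresponding names when names were supplied.
    ``trace`` records every decision as ``(action, candidate, criterion)``
    tuples so a run can be audited and replayed.
    """

    method: str
    selected: list[int]
    selected_names: list[str] = field(default_factory=list)
    trace: list[tuple[str, str, float]] = field(default_factory=list)


def constant_redundant_filter(table: DescriptorTable) -> DescriptorTable:
    """Drop zero-variance columns and exact duplicates (keeping first seen)."""
    keep: list[str] = []
    seen: list[np.ndarray] = []
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        if np.all(col == col[0]):
            continue
        if any(np.array_equal(col, prev) for prev in seen):
            continue
        keep.append(name)
        seen.append(col)
    if not keep:
        raise SelectionError("all descriptor columns are constant or redundant")
    return table.select_columns(keep)


# ---------------------------------------------------------------------------
# Stepwise MLR


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def _partial_f_pvalue(
    X_small: np.ndarray, X_big: np.ndarray, y: np.ndarray
) -> float:
    """p-value of the partial F-test for the one extra column in X_big."""
    n = len(y)
    p_big = X_big.shape[1]
    df2 = n - p_big - 1  # intercept included
    if df2 <= 0:
        return 1.0
    rss_small = _rss(X_small, y)
    rss_big = _rss(X_big, y)
    tol = 1e-10 * (float(y @ y) + 1.0)
    if rss_big <= tol:
        # exact (or numerically exact) fit: the candidate only matters if the
        # smaller model had residual error left to explain
        return 0.0 if rss_small > tol else 1.0
    f = (rss_small - rss_big) / (rss_big / df2)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, df2))


def _is_collinear(X: np.ndarray) -> bool:
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    return np.linalg.matrix_rank(design) < design.shape[1]


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    names: list[str] | None = None,
    max_steps: int = 1000,
) -> SelectionResult:
    """Classical forward-entry / backward-removal stepwise regression.

    At each round the candidate with the smallest partial-F p-value enters
    if it is below ``alpha_enter``; entered variables whose p-value (given
    the rest) rises above ``alpha_remove`` are removed.  Ties break by
    column order.  Terminates when no move is possible (a cycle cannot occur
    because alpha_enter <= alpha_remove).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if p == 0:
        raise SelectionError("no candidate columns")
    if n < 3:
        raise SelectionError("need at least 3 samples")
    if not alpha_enter <= alpha_remove:
        raise SelectionError("alpha_enter must be <= alpha_remove")
    names = names or [f"x{j}" for j in range(p)]

    selected: list[int] = []
    trace: list[tuple[str, str, float]] = []
    for _ in range(max_steps):
        moved = False
        # forward step
        best_j, best_p = None, 1.0
        for j in range(p):
            if j in selected:
                continue
            cand = X[:, selected + [j]]
            if _is_collinear(cand):
                trace.append(("skip-collinear", names[j], float("nan")))
                continue
            pval = _partial_f_pvalue(X[:, selected], cand, y)
            if pval < best_p:
                best_j, best_p = j, pval
        if best_j is not None and best_p < alpha_enter:
            selected.append(best_j)
            trace.append(("enter", names[best_j], best_p))
            moved = True
        # backward step
        while len(selected) > 1:
            worst_j, worst_p = None, -1.0
            for j in selected:
                rest = [k for k in selected if k != j]
                pval = _partial_f_pvalue(X[:, rest], X[:, rest + [j]], y)
                if pval > worst_p:
                    worst_j, worst_p = j, pval
            if worst_j is not None and worst_p > alpha_remove:
                selected.remove(worst_j)
                trace.append(("remove", names[worst_j], worst_p))
                moved = True
            else:
                break
        if not moved:
            break
    return SelectionResult(
        method="stepwise",
        selected=list(selected),
        selected_names=[names[j] for j in selected],
        trace=trace,
    )


# ---------------------------------------------------------------------------
# CFS + best-first


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def cfs_merit(subset: tuple[int, ...], rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit: k*mean|r_cf| / sqrt(k + k(k-1)*mean|r_ff|).

    Rewards feature-class correlation, penalises feature-feature redundancy.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    mean_cf = float(np.mean([rcf[j] for j in subset]))
    if k == 1:
        mean_ff = 0.0
    else:
        pairs = list(itertools.combinations(subset, 2))
        mean_ff = float(np.mean([rff[a, b] for a, b in pairs]))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_bestfirst(
    X: np.ndarray,
    y: np.ndarray,
    stale_limit: int = 5,
    names: list[str] | None = None,
) -> SelectionResult:
    """Best-first forward search over descriptor subsets maximising CFS merit.

    Expansion order is by merit (ties broken by subset column order, making
    the search deterministic); the search stops after ``stale_limit``
    consecutive expansions that fail to improve on the best subset found.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if p == 0:
        raise SelectionError("no candidate columns")
    if n < 3:
        raise SelectionError("need at least 3 samples")
    names = names or [f"x{j}" for j in range(p)]

    rcf = np.array([_abs_corr(X[:, j], y) for j in range(p)])
    rff = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            rff[a, b] = rff[b, a] = _abs_corr(X[:, a], X[:, b])

    start: tuple[int, ...] = ()
    best_subset, best_merit = start, 0.0
    # heap keyed by (-merit, subset) so higher merit pops first, ties by order
    frontier: list[tuple[float, tuple[int, ...]]] = [(-0.0, start)]
    visited: set[tuple[int, ...]] = {start}
    trace: list[tuple[str, str, float]] = []
    stale = 0
    while frontier and stale < stale_limit:
        neg_merit, subset = heapq.heappop(frontier)
        improved = False
        for j in range(p):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, rcf, rff)
            trace.append(("evaluate", ",".join(names[i] for i in child), merit))
            heapq.heappush(frontier, (-merit, child))
            if merit > best_merit:
                best_subset, best_merit = child, merit
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
    selected = list(best_subset)
    return SelectionResult(
        method="cfs_bestfirst",
        selected=selected,
        selected_names=[names[j] for j in selected],
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Intercorrelation


def intercorrelation_check(
    table: DescriptorTable, cutoff: float = 0.9
) -> tuple[np.ndarray, bool]:
    """Pairwise Pearson r among selected descriptors and an independence verdict.

    Returns ``(r_matrix, passed)`` where ``passed`` is True iff every
    off-diagonal |r| <= cutoff.  A zero-variance column makes r undefined
    and is reported as an error rather than silently passed.
    """
    if table.n_descriptors < 2:
        raise SelectionError("need at least 2 selected descriptors")
    stds = table.values.std(axis=0)
    bad = [n for n, s in zip(table.descriptor_names, stds) if s == 0]
    if bad:
        raise SelectionError(f"zero-variance descriptor(s): {bad} — r undefined")
    r = np.corrcoef(table.values, rowvar=False)
    off = r[~np.eye(table.n_descriptors, dtype=bool)]
    return r, bool(np.all(np.abs(off) <= cutoff))
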