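"""Gain-ratio decision-tree classification (C4.5/J48 style).

Binary active/inactive QSPR classification over continuous descriptors:
candidate thresholds are midpoints between consecutive distinct sorted
values, splits are chosen by maximal information gain ratio, rows route
left on value <= threshold and right on value > threshold, and recursion
stops at purity, the minimum-leaf size, or when no split has positive gain.
Trees are unpruned by default, matching the shape class of small-n QSPR
trees.

:func:`published_tree` carries the two-level antimicrobial rule of the
source study (root X4sol at 7.564, internal node VR2_Dzi at 11.729) as a
fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .tables import DescriptorTable, TableFormatError, _json_dump, _json_load

__all__ = [
    "Leaf",
    "Split",
    "TreeModel",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "induce_tree",
    "published_tree",
    "apply_tree",
    "classification_metrics",
    "cv_classification",
    "write_tree_model",
    "read_tree_model",
]

ACTIVE = "active"
INACTIVE = "inactive"
CLASSES = (ACTIVE, INACTIVE)


@dataclass(frozen=True)
class Leaf:
    class_label: str
    n_correct: int = 0
    n_incorrect: int = 0


@dataclass(frozen=True)
class Split:
    descriptor_name: str
    threshold: float
    left: "TreeNode"   # value <= threshold
    right: "TreeNode"  # value > threshold

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("split threshold must be finite")


TreeNode = Union[Leaf, Split]


@dataclass(frozen=True)
class TreeModel:
    """A binary threshold tree with class leaves."""

    root: TreeNode

    def descriptors_used(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if isinstance(node, Split):
                if node.descriptor_name not in names:
                    names.append(node.descriptor_name)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return names

    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            if isinstance(node, Leaf):
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)


# ---------------------------------------------------------------------------
# Induction


def _entropy(labels: np.ndarray) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    h = 0.0
    for c in np.unique(labels):
        frac = float(np.sum(labels == c)) / n
        h -= frac * math.log2(frac)
    return h


def _gain_ratio(
    values: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(information gain, gain ratio) of splitting at value <= threshold."""
    left = values <= threshold
    n = len(labels)
    n_left = int(left.sum())
    if n_left == 0 or n_left == n:
        return 0.0, 0.0
    h_parent = _entropy(labels)
    gain = h_parent - (
        n_left / n * _entropy(labels[left])
        + (n - n_left) / n * _entropy(labels[~left])
    )
    fl = n_left / n
    split_info = -(fl * math.log2(fl) + (1 - fl) * math.log2(1 - fl))
    return gain, gain / split_info


def candidate_splits(
    X: np.ndarray, labels: np.ndarray, min_leaf: int
) -> list[tuple[int, float, float, float]]:
    """Enumerate (column, threshold, gain, gain_ratio) for admissible splits."""
    out = []
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            left_n = int(np.sum(X[:, j] <= thr))
            if left_n < min_leaf or len(labels) - left_n < min_leaf:
                continue
            gain, ratio = _gain_ratio(X[:, j], labels, thr)
            out.append((j, thr, gain, ratio))
    return out


def _best_split(
    X: np.ndarray, labels: np.ndarray, min_leaf: int
) -> tuple[int, float] | None:
    best = None
    best_key = (-1.0, 0, 0.0)  # (gain_ratio, -column, -threshold) maximised
    for j, thr, gain, ratio in candidate_splits(X, labels, min_leaf):
        if gain <= 1e-12:
            continue
        key = (ratio, -j, -thr)  # ties: earlier column, lower threshold
        if key > best_key:
            best_key = key
            best = (j, thr)
    return best


def _majority_leaf(labels: np.ndarray) -> Leaf:
    values, counts = np.unique(labels, return_counts=True)
    # count ties break toward 'active' (the positive class)
    best = max(zip(counts, [-CLASSES.index(v) for v in values], values))[2]
    label = str(best)
    correct = int(np.sum(labels == label))
    return Leaf(label, n_correct=correct, n_incorrect=len(labels) - correct)


def induce_tree(
    table: DescriptorTable,
    classes: Sequence[str],
    min_leaf: int = 2,
) -> TreeModel:
    """Grow an unpruned gain-ratio tree on a descriptor table.

    ``classes`` must be 'active'/'inactive' labels aligned with the table's
    rows.  A single-class dataset yields a single-leaf tree.
    """
    labels = np.asarray([str(c) for c in classes])
    bad = set(labels) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    if len(labels) != table.n_compounds:
        raise ValueError("class vector length does not match table rows")
    if table.n_descriptors == 0:
        raise ValueError("no descriptors to split on")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    X = np.asarray(table.values)
    names = table.descriptor_names

    def grow(rows: np.ndarray) -> TreeNode:
        sub_labels = labels[rows]
        if len(np.unique(sub_labels)) == 1 or len(rows) < 2 * min_leaf:
            return _majority_leaf(sub_labels)
        choice = _best_split(X[rows], sub_labels, min_leaf)
        if choice is None:
            return _majority_leaf(sub_labels)
        j, thr = choice
        left_mask = X[rows, j] <= thr
        return Split(
            descriptor_name=names[j],
            threshold=thr,
            left=grow(rows[left_mask]),
            right=grow(rows[~left_mask]),
        )

    return TreeModel(root=grow(np.arange(len(labels))))


def published_tree() -> TreeModel:
    """The published two-level antimicrobial classification rule.

    Root: X4sol <= 7.564 -> active; else VR2_Dzi <= 11.729 -> inactive,
    VR2_Dzi > 11.729 -> active.  Leaf counts reflect the 11-compound
    training panel (one inactive routed to the deep active leaf).
    """
    return TreeModel(
        root=Split(
            descriptor_name="X4sol",
            threshold=7.564,
            left=Leaf(ACTIVE, n_correct=5, n_incorrect=0),
            right=Split(
                descriptor_name="VR2_Dzi",
                threshold=11.729,
                left=Leaf(INACTIVE, n_correct=3, n_incorrect=0),
                right=Leaf(ACTIVE, n_correct=2, n_incorrect=1),
            ),
        )
    )


def apply_tree(tree: TreeModel, table: DescriptorTable) -> list[str]:
    """Route each table row through the tree; value == threshold goes left."""
    for name in tree.descriptors_used():
        table.resolve(name)  # raises KeyError naming the missing descriptor
    out = []
    for i in range(table.n_compounds):
        node = tree.root
        while isinstance(node, Split):
            val = table.column(node.descriptor_name)[i]
            node = node.left if val <= node.threshold else node.right
        out.append(node.class_label)
    return out


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with 'active' as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy (%) plus class-support-weighted precision/recall/F-measure."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    undefined_precision: bool = False


def _per_class(actual: np.ndarray, predicted: np.ndarray, label: str):
    tp = int(np.sum((actual == label) & (predicted == label)))
    fp = int(np.sum((actual != label) & (predicted == label)))
    fn = int(np.sum((actual == label) & (predicted != label)))
    support = int(np.sum(actual == label))
    undefined = (tp + fp) == 0
    prec = 0.0 if undefined else tp / (tp + fp)
    rec = 0.0 if support == 0 else tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1, support, undefined


def classification_metrics(
    actual: Sequence[str],
    predicted: Sequence[str],
    average: str = "weighted",
) -> tuple[ConfusionMatrix, ClassificationMetrics]:
    """Confusion matrix and summary metrics.

    Per-class precision/recall/F1 are computed for both classes and combined
    by class-support weights (default) or unweighted macro average.  A class
    never predicted has precision 0 and sets the ``undefined_precision``
    flag.
    """
    act = np.asarray([str(a) for a in actual])
    pred = np.asarray([str(p) for p in predicted])
    if len(act) == 0 or len(act) != len(pred):
        raise ValueError("actual and predicted must have equal nonzero length")
    bad = (set(act) | set(pred)) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    cm = ConfusionMatrix(
        tp=int(np.sum((act == ACTIVE) & (pred == ACTIVE))),
        fp=int(np.sum((act == INACTIVE) & (pred == ACTIVE))),
        tn=int(np.sum((act == INACTIVE) & (pred == INACTIVE))),
        fn=int(np.sum((act == ACTIVE) & (pred == INACTIVE))),
    )
    n = len(act)
    accuracy = 100.0 * (cm.tp + cm.tn) / n
    rows = [_per_class(act, pred, label) for label in CLASSES]
    undefined = any(r[4] and r[3] > 0 for r in rows)
    if average == "weighted":
        weights = [r[3] / n for r in rows]
    elif average == "macro":
        present = [r for r in rows if r[3] > 0]
        weights = [1.0 / len(present) if r[3] > 0 else 0.0 for r in rows]
    else:
        raise ValueError(f"unknown averaging {average!r}")
    precision = sum(w * r[0] for w, r in zip(weights, rows))
    recall = sum(w * r[1] for w, r in zip(weights, rows))
    f_measure = sum(w * r[2] for w, r in zip(weights, rows))
    return cm, ClassificationMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        undefined_precision=undefined,
    )


# ---------------------------------------------------------------------------
# Cross-validated classification


def stratified_kfold_assignment(
    labels: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Seeded stratified partition: each class spread as evenly as possible."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[i] = pos % k
    return folds


def cv_classification(
    table: DescriptorTable,
    classes: Sequence[str],
    scheme: str = "loo",
    k: int = 5,
    seed: int = 0,
    min_leaf: int = 2,
    trace: list | None = None,
) -> tuple[ConfusionMatrix, ClassificationMetrics]:
    """Cross-validated tree classification with pooled out-of-fold predictions.

    ``scheme`` is 'loo' or 'kfold' (stratified, seeded).  A training fold
    containing a single class yields a single-leaf tree, which is valid.
    ``trace``, if supplied, collects the per-fold induced trees.
    """
    labels = np.asarray([str(c) for c in classes])
    n = table.n_compounds
    if len(labels) != n:
        raise ValueError("class vector length does not match table rows")
    if scheme == "loo":
        folds = np.arange(n)
        n_folds = n
    elif scheme == "kfold":
        folds = stratified_kfold_assignment(labels, k, seed)
        n_folds = k
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    predictions = np.empty(n, dtype=object)
    ids = list(table.compound_ids)
    for f in range(n_folds):
        test = folds == f
        train_ids = [ids[i] for i in np.flatnonzero(~test)]
        test_ids = [ids[i] for i in np.flatnonzero(test)]
        sub = table.select_rows(train_ids)
        tree = induce_tree(sub, labels[~test], min_leaf=min_leaf)
        if trace is not None:
            trace.append(tree)
        predictions[test] = apply_tree(tree, table.select_rows(test_ids))
    return classification_metrics(labels, [str(p) for p in predictions])


# ---------------------------------------------------------------------------
# JSON serialization


def _node_to_dict(node: TreeNode) -> dict:
    if isinstance(node, Leaf):
        return {
            "leaf": node.class_label,
            "n_correct": node.n_correct,
            "n_incorrect": node.n_incorrect,
        }
    return {
        "descriptor": node.descriptor_name,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),   # value <= threshold
        "right": _node_to_dict(node.right),  # value > threshold
    }


def _node_from_dict(data: dict) -> TreeNode:
    if "leaf" in data:
        return Leaf(
            str(data["leaf"]),
            int(data.get("n_correct", 0)),
            int(data.get("n_incorrect", 0)),
        )
    return Split(
        descriptor_name=str(data["descriptor"]),
        threshold=float(data["threshold"]),
        left=_node_from_dict(data["left"]),
        right=_node_from_dict(data["right"]),
    )


def write_tree_model(tree: TreeModel, path: str | Path) -> None:
    _json_dump({"type": "tree_model", "root": _node_to_dict(tree.root)}, path)


def read_tree_model(path: str | Path) -> TreeModel:
    data = _json_load(path)
    try:
        return TreeModel(root=_node_from_dict(data["root"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise TableFormatError(f"{path}: malformed tree model ({exc})") from exc
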