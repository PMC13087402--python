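import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

from qsarkit import (
    DescriptorTable,
    apply_tree,
    classification_metrics,
    cv_classification,
    induce_tree,
    published_tree,
    read_tree_model,
    write_tree_model,
)
from qsarkit.simulate import ClassificationScenario, gen_classification
from qsarkit.tree import Leaf, Split, candidate_splits


def oracle_entropy(labels):
    n = len(labels)
    h = 0.0
    for c in set(labels):
        f = labels.count(c) / n
        h -= f * math.log2(f)
    return h


def oracle_best_split(table, labels, min_leaf=1):
    """Exhaustive (descriptor, threshold) search by gain ratio, written from
    first principles independently of the induction code."""
    best = None
    X = np.asarray(table.values)
    lab = list(labels)
    h_parent = oracle_entropy(lab)
    for j, name in enumerate(table.descriptor_names):
        vals = sorted(set(X[:, j]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [l for x, l in zip(X[:, j], lab) if x <= thr]
            right = [l for x, l in zip(X[:, j], lab) if x > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = h_parent - (
                len(left) / len(lab) * oracle_entropy(left)
                + len(right) / len(lab) * oracle_entropy(right)
            )
            if gain <= 1e-12:
                continue
            fl = len(left) / len(lab)
            split_info = -(fl * math.log2(fl) + (1 - fl) * math.log2(1 - fl))
            ratio = gain / split_info
            key = (ratio, -j, -thr)
            if best is None or key > best[0]:
                best = (key, name, thr)
    return None if best is None else (best[1], best[2])


class TestInduction:
    def test_separable_1d_single_midpoint_split(self):
        table = DescriptorTable(
            [f"c{i}" for i in range(6)],
            ["d"],
            [[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]],
        )
        classes = ["active"] * 3 + ["inactive"] * 3
        tree = induce_tree(table, classes, min_leaf=1)
        assert isinstance(tree.root, Split)
        assert tree.root.threshold == pytest.approx(5.0)
        assert apply_tree(tree, table) == classes

    def test_two_level_rule_recovered(self):
        scen = ClassificationScenario(n_compounds=40, n_active=24, margin=0.6, seed=5)
        table, classes = gen_classification(scen)
        tree = induce_tree(table, classes, min_leaf=1)
        assert apply_tree(tree, table) == classes  # 100% training accuracy
        assert tree.descriptors_used()[0] in {scen.descriptor1, scen.descriptor2}
        assert set(tree.descriptors_used()) <= {scen.descriptor1, scen.descriptor2}

    @pytest.mark.parametrize("seed", range(5))
    def test_chosen_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        table = DescriptorTable(
            [f"c{i}" for i in range(n)],
            ["a", "b", "c"],
            rng.integers(0, 6, size=(n, 3)).astype(float),
        )
        classes = [["active", "inactive"][i] for i in rng.integers(0, 2, n)]
        if len(set(classes)) == 1:
            classes[0] = "active" if classes[0] == "inactive" else "inactive"
        tree = induce_tree(table, classes, min_leaf=1)
        oracle = oracle_best_split(table, classes, min_leaf=1)
        if oracle is None:
            assert isinstance(tree.root, Leaf)
        else:
            assert isinstance(tree.root, Split)
            assert (tree.root.descriptor_name, tree.root.threshold) == (
                oracle[0],
                pytest.approx(oracle[1]),
            )

    def test_single_class_gives_single_leaf(self, small_table):
        tree = induce_tree(small_table, ["active"] * 3)
        assert isinstance(tree.root, Leaf)
        assert tree.root.class_label == "active"

    def test_min_leaf_respected(self):
        table = DescriptorTable(
            [f"c{i}" for i in range(4)], ["d"], [[1.0], [2.0], [3.0], [4.0]]
        )
        classes = ["active", "inactive", "active", "inactive"]
        tree = induce_tree(table, classes, min_leaf=2)
        if isinstance(tree.root, Split):
            assert all(
                c[0] is not None for c in candidate_splits(
                    np.asarray(table.values), np.asarray(classes), 2
                )
            )


class TestPublishedTree:
    @pytest.mark.parametrize(
        "x4sol,vr2,expected",
        [
            (7.0, 5.0, "active"),     # shallow active leaf
            (8.0, 11.0, "inactive"),  # low ionization-potential branch
            (8.0, 12.0, "active"),    # deep active leaf
            (7.564, 0.0, "active"),   # value == threshold routes left
        ],
    )
    def test_routing(self, x4sol, vr2, expected):
        table = DescriptorTable(["c"], ["X4sol", "VR2_Dzi"], [[x4sol, vr2]])
        assert apply_tree(published_tree(), table) == [expected]

    def test_predictions_invariant_to_extra_columns(self, tree_table):
        preds = apply_tree(published_tree(), tree_table)
        stripped = tree_table.select_columns(["X4sol", "VR2_Dzi"])
        assert apply_tree(published_tree(), stripped) == preds

    def test_missing_descriptor_error_names_it(self):
        table = DescriptorTable(["c"], ["X4sol"], [[7.0]])
        with pytest.raises(KeyError, match="VR2_Dzi"):
            apply_tree(published_tree(), table)

    def test_json_round_trip(self, tmp_path):
        tree = published_tree()
        path = tmp_path / "tree.json"
        write_tree_model(tree, path)
        assert read_tree_model(path) == tree


class TestClassificationMetrics:
    def test_worked_training_example(self):
        ids = [str(i) for i in range(3, 14)]
        actual_active = {"3", "4", "5", "6", "8", "10", "12"}
        predicted_active = actual_active | {"7"}
        actual = ["active" if c in actual_active else "inactive" for c in ids]
        pred = ["active" if c in predicted_active else "inactive" for c in ids]
        cm, m = classification_metrics(actual, pred)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (7, 1, 3, 0)
        assert round(m.accuracy, 2) == 90.91
        assert round(m.precision, 3) == 0.920
        assert round(m.recall, 3) == 0.909
        assert round(m.f_measure, 3) == 0.906

    def test_perfect_prediction(self):
        labels = ["active", "inactive", "active"]
        _, m = classification_metrics(labels, labels)
        assert m.accuracy == 100.0
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_weighted_averages(self, seed):
        rng = np.random.default_rng(seed)
        actual = [["active", "inactive"][i] for i in rng.integers(0, 2, 30)]
        pred = [["active", "inactive"][i] for i in rng.integers(0, 2, 30)]
        _, m = classification_metrics(actual, pred)
        p, r, f, _ = precision_recall_fscore_support(
            actual, pred, average="weighted", zero_division=0
        )
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f_measure == pytest.approx(f)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_weighted_recall_equals_accuracy(self, pairs):
        actual = ["active" if a else "inactive" for a, _ in pairs]
        pred = ["active" if p else "inactive" for _, p in pairs]
        _, m = classification_metrics(actual, pred)
        assert m.recall * 100 == pytest.approx(m.accuracy)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(["active"], ["maybe"])


class TestCVClassification:
    def test_wide_margin_data_scores_100_loo(self):
        # margin large relative to the residual spread beyond it, so no
        # leave-one-out refit can shift a midpoint past the held-out point
        scen = ClassificationScenario(
            n_compounds=24, n_active=14, margin=1.2, spread=1.3, seed=2
        )
        table, classes = gen_classification(scen)
        _, m = cv_classification(table, classes, scheme="loo", min_leaf=1)
        assert m.accuracy == 100.0

    def test_loo_performs_n_inductions(self, tree_table):
        trace = []
        cv_classification(
            tree_table, ["active", "inactive", "active", "active"],
            scheme="loo", min_leaf=1, trace=trace,
        )
        assert len(trace) == 4

    def test_boundary_adjacent_points_drop_cv_below_training(self):
        # tight margins: each left-out boundary point tends to flip its side,
        # reproducing the direction of the training -> CV accuracy drop
        drops = 0
        for seed in range(6):
            scen = ClassificationScenario(
                n_compounds=11, n_active=7, margin=0.01, spread=0.4, seed=seed
            )
            table, classes = gen_classification(scen)
            tree = induce_tree(table, classes, min_leaf=1)
            _, train = classification_metrics(classes, apply_tree(tree, table))
            _, cv = cv_classification(table, classes, scheme="loo", min_leaf=1)
            assert cv.accuracy <= train.accuracy
            drops += cv.accuracy < train.accuracy
        assert drops >= 4

    def test_stratified_kfold_deterministic_given_seed(self):
        scen = ClassificationScenario(n_compounds=20, n_active=12, seed=9)
        table, classes = gen_classification(scen)
        a = cv_classification(table, classes, scheme="kfold", k=5, seed=3)
        b = cv_classification(table, classes, scheme="kfold", k=5, seed=3)
        assert a[1] == b[1]
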