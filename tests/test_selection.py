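import itertools

import numpy as np
import pytest

from qsarkit import (
    DescriptorTable,
    cfs_bestfirst,
    constant_redundant_filter,
    intercorrelation_check,
    stepwise_select,
)
from qsarkit.selection import SelectionError, _abs_corr, cfs_merit


class TestConstantRedundantFilter:
    def test_constant_and_duplicate_columns_removed(self, rng):
        base = rng.standard_normal((8, 3))
        values = np.column_stack([base, np.full(8, 2.5), base[:, 1]])
        table = DescriptorTable(
            [f"c{i}" for i in range(8)], ["a", "b", "c", "const", "dup_b"], values
        )
        out = constant_redundant_filter(table)
        assert out.descriptor_names == ("a", "b", "c")

    def test_survivors_match_brute_force_scan(self, rng):
        values = rng.integers(0, 3, size=(6, 10)).astype(float)
        values[:, 4] = 7.0
        values[:, 8] = values[:, 2]
        table = DescriptorTable(
            [f"c{i}" for i in range(6)], [f"d{j}" for j in range(10)], values
        )
        # brute force: first occurrence of each distinct non-constant column
        expected = []
        seen = []
        for j in range(10):
            col = tuple(values[:, j])
            if len(set(col)) == 1 or col in seen:
                continue
            seen.append(col)
            expected.append(f"d{j}")
        assert list(constant_redundant_filter(table).descriptor_names) == expected

    def test_all_removed_is_an_error(self):
        table = DescriptorTable(["a", "b"], ["x", "y"], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SelectionError):
            constant_redundant_filter(table)


class TestStepwise:
    def test_planted_signal_recovered_exactly(self, rng):
        X = rng.standard_normal((40, 10))
        y = 2.0 * X[:, 3] - 5.0 * X[:, 6]  # no noise
        res = stepwise_select(X, y)
        assert sorted(res.selected) == [3, 6]
        assert all(action in {"enter", "remove", "skip-collinear"} for action, *_ in res.trace)

    def test_pure_noise_rarely_admits_variables(self):
        # expected false entries ~ alpha per candidate; over 20 replicates the
        # mean selected-set size must stay well below 1 informative variable
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((50, 10))
            y = rng.standard_normal(50)
            sizes.append(len(stepwise_select(X, y).selected))
        assert np.mean(sizes) < 1.5

    def test_zero_variance_column_never_selected(self, rng):
        X = rng.standard_normal((30, 5))
        X[:, 2] = 4.0
        y = 3.0 * X[:, 0] + rng.normal(0, 0.01, 30)
        res = stepwise_select(X, y)
        assert 2 not in res.selected

    def test_selection_invariant_to_row_order(self, rng):
        X = rng.standard_normal((30, 8))
        y = 1.5 * X[:, 1] - 2.0 * X[:, 5] + rng.normal(0, 0.05, 30)
        res = stepwise_select(X, y)
        perm = rng.permutation(30)
        res_perm = stepwise_select(X[perm], y[perm])
        assert res.selected == res_perm.selected

    def test_no_columns_is_an_error(self):
        with pytest.raises(SelectionError):
            stepwise_select(np.empty((10, 0)), np.zeros(10))


class TestCFS:
    def test_perfect_single_predictor_wins(self, rng):
        X = rng.standard_normal((30, 6))
        y = X[:, 4].copy()
        res = cfs_bestfirst(X, y)
        assert res.selected == [4]

    def test_bestfirst_equals_exhaustive_enumeration(self, rng):
        X = rng.standard_normal((25, 4))
        y = 1.0 * X[:, 0] + 0.8 * X[:, 2] + rng.normal(0, 0.3, 25)
        res = cfs_bestfirst(X, y)
        rcf = np.array([_abs_corr(X[:, j], y) for j in range(4)])
        rff = np.zeros((4, 4))
        for a, b in itertools.combinations(range(4), 2):
            rff[a, b] = rff[b, a] = _abs_corr(X[:, a], X[:, b])
        best = max(
            (
                subset
                for r in range(1, 5)
                for subset in itertools.combinations(range(4), r)
            ),
            key=lambda s: cfs_merit(s, rcf, rff),
        )
        assert tuple(sorted(res.selected)) == best

    def test_duplicated_informative_column_enters_once(self, rng):
        x = rng.standard_normal(30)
        noise = rng.standard_normal((30, 3))
        X = np.column_stack([x, x, noise])
        y = x + rng.normal(0, 0.05, 30)
        res = cfs_bestfirst(X, y)
        assert len(set(res.selected) & {0, 1}) == 1


class TestIntercorrelation:
    def test_identical_columns_fail(self, rng):
        x = rng.standard_normal(10)
        table = DescriptorTable(
            [f"c{i}" for i in range(10)], ["a", "b"], np.column_stack([x, x])
        )
        r, passed = intercorrelation_check(table, cutoff=0.9)
        assert not passed
        assert r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_columns_pass(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        table = DescriptorTable(
            ["w", "x", "y", "z"], ["a", "b"], np.column_stack([a, b])
        )
        r, passed = intercorrelation_check(table, cutoff=0.9)
        assert passed
        assert r[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_matches_direct_formula(self, rng):
        values = rng.standard_normal((12, 4))
        table = DescriptorTable(
            [f"c{i}" for i in range(12)], list("abcd"), values
        )
        r, _ = intercorrelation_check(table)
        for i, j in itertools.combinations(range(4), 2):
            x, y = values[:, i], values[:, j]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert r[i, j] == pytest.approx(num / den, rel=1e-12)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_zero_variance_column_flagged(self):
        table = DescriptorTable(
            ["a", "b", "c"], ["x", "y"], [[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]
        )
        with pytest.raises(SelectionError, match="zero-variance"):
            intercorrelation_check(table)
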