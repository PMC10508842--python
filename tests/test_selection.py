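"""Pruning, mRMR and the rank-sum test against enumeration oracles."""

from itertools import permutations

import numpy as np
import pytest

from deltarad.selection import (discretize_three_state, mrmr_select,
                                mutual_information, prune_correlated,
                                wilcoxon_rank_sum)

from _oracles import mi_oracle, ranksum_exact_oracle


class TestPrune:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=(10, 1))
        X = np.hstack([x, x])
        assert prune_correlated(X, ["a", "b"], 0.9) == ["a"]

    def test_uncorrelated_columns_retained(self, rng):
        X = rng.normal(size=(200, 6))
        names = list("abcdef")
        assert prune_correlated(X, names, 0.9) == names

    def test_copies_and_negations_pruned(self, rng):
        c1 = rng.normal(size=50)
        c2 = rng.normal(size=50)
        c4 = rng.normal(size=50)
        X = np.column_stack([c1, c2, c1, c4, -c2])
        names = ["f1", "f2", "f3", "f4", "f5"]
        assert prune_correlated(X, names, 0.9) == ["f1", "f2", "f4"]

    def test_constant_columns_dropped_first(self, rng):
        X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
        assert prune_correlated(X, ["const", "var"], 0.9) == ["var"]

    def test_retained_set_has_no_high_correlation(self, rng):
        base = rng.normal(size=(30, 4))
        mix = base @ rng.normal(size=(4, 20)) + 0.3 * rng.normal(size=(30, 20))
        names = [f"f{i}" for i in range(20)]
        kept = prune_correlated(mix, names, 0.9)
        idx = [names.index(n) for n in kept]
        R = np.corrcoef(mix[:, idx], rowvar=False)
        off = R[~np.eye(len(idx), dtype=bool)]
        assert np.all(np.abs(off) < 0.9)


class TestMrmr:
    def test_k1_reduces_to_max_relevance(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        X = np.column_stack([rng.normal(size=n),
                             y + 0.1 * rng.normal(size=n),
                             rng.normal(size=n)])
        assert mrmr_select(X, y, ["a", "b", "c"], k=1) == ["b"]

    def test_exact_duplicate_never_picked_second(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        strong = y + 0.2 * rng.normal(size=n)
        weak = y + 1.5 * rng.normal(size=n)
        X = np.column_stack([strong, strong, weak])
        sel = mrmr_select(X, y, ["s1", "s1_copy", "w"], k=2)
        assert sel[0] == "s1"
        assert sel[1] == "w"

    def test_redundancy_weight_zero_is_topk_by_mi(self, rng):
        n, p = 50, 8
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p)) + y[:, None] * rng.normal(size=p)
        names = [f"f{i}" for i in range(p)]
        sel = mrmr_select(X, y, names, k=4, redundancy_weight=0.0)
        D = discretize_three_state(X)
        mis = [mutual_information(D[:, j], y) for j in range(p)]
        expect = [names[j] for j in np.argsort(-np.asarray(mis), kind="stable")[:4]]
        assert sel == expect

    def test_greedy_path_matches_exhaustive_enumeration(self, rng):
        # 6 features, k=3: recompute the greedy argmax at every stage with an
        # independent MI implementation, enumerating all candidates
        n, p, k = 30, 6, 3
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p))
        X[:, 0] += 1.2 * y
        X[:, 1] += 1.1 * y
        X[:, 2] = X[:, 0] + 0.1 * rng.normal(size=n)
        names = [f"f{i}" for i in range(p)]
        got = mrmr_select(X, y, names, k=k)

        D = discretize_three_state(X)
        cols = {names[j]: list(D[:, j]) for j in range(p)}
        selected = []
        for _ in range(k):
            best_name, best_score = None, -np.inf
            for name in names:
                if name in selected:
                    continue
                rel = mi_oracle(cols[name], list(y))
                red = (np.mean([mi_oracle(cols[name], cols[s])
                                for s in selected]) if selected else 0.0)
                score = rel - red
                if score > best_score + 1e-12:
                    best_name, best_score = name, score
            selected.append(best_name)
        assert got == selected

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            mrmr_select(X, np.zeros(10, int), ["a", "b", "c"], k=2)
        with pytest.raises(ValueError):
            mrmr_select(X, np.r_[np.zeros(5, int), np.ones(5, int)],
                        ["a", "b", "c"], k=0)


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        # 2 extreme assignments out of C(6,3)=20 -> two-sided p = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=7)
        b = rng.normal(size=8)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            wilcoxon_rank_sum(a + 13.7, b + 13.7))

    @pytest.mark.parametrize("na,nb,seed", [(3, 4, 0), (5, 5, 1), (6, 6, 2),
                                            (4, 8, 3)])
    def test_exact_branch_matches_full_enumeration(self, na, nb, seed):
        r = np.random.default_rng(seed)
        a = r.permutation(np.arange(na + nb) * 1.37)[:na]
        b = np.setdiff1d(np.arange(na + nb) * 1.37, a)
        got = wilcoxon_rank_sum(a, b)
        want = ranksum_exact_oracle(list(a), list(b))
        assert got == pytest.approx(want)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestMutualInformation:
    def test_symmetry_and_nonnegativity(self, rng):
        x = rng.integers(0, 3, 60)
        y = rng.integers(0, 2, 60)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x))
        assert mutual_information(x, y) >= 0.0

    def test_matches_plugin_oracle(self, rng):
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 2, 40)
        assert mutual_information(x, y) == pytest.approx(
            mi_oracle(list(x), list(y)))

    def test_deterministic_function_has_full_information(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
        assert mutual_information(x, x) == pytest.approx(
            np.log2(3), abs=1e-12)
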