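import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dtcsig import (SamConfig, sam_statistic, top_bottom_k, top_variable_genes,
                    welch_tests)

from conftest import make_matrix


def pooled_t_oracle(x1, x2):
    """Hand-coded pooled two-sample statistic: (m1-m2)/sqrt(sp2*(1/n1+1/n2))."""
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    return (np.mean(x1) - np.mean(x2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def two_group_matrix(n_genes=40, n1=4, n2=4, seed=0, shift_first=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, n1 + n2))
    X[0, :n1] += shift_first
    cells = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    m = make_matrix(X, cells=cells)
    groups = pd.Series({c: ("g1" if c.startswith("a") else "g2") for c in cells})
    return m, groups


class TestSam:
    def test_identical_groups_give_zero_d(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 8))
        cells = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        m = make_matrix(X, cells=cells)
        groups = pd.Series({c: c[0] for c in cells})
        tab = sam_statistic(m, groups, SamConfig(s0=0.1, n_permutations=10, seed=1))
        assert np.allclose(tab["d"], 0.0)

    def test_s0_zero_matches_pooled_t_oracle(self):
        m, groups = two_group_matrix(seed=3)
        tab = sam_statistic(m, groups, SamConfig(s0=0.0, n_permutations=10, seed=1))
        X = m.values
        for g in tab.index:
            expected = pooled_t_oracle(X.loc[g].iloc[:4].to_numpy(),
                                       X.loc[g].iloc[4:].to_numpy())
            assert abs(tab.at[g, "d"] - expected) < 1e-12

    def test_label_swap_negates_d_and_preserves_q(self):
        m, groups = two_group_matrix(seed=4, shift_first=3.0)
        cfg = SamConfig(s0=0.05, n_permutations=200, seed=2)
        tab = sam_statistic(m, groups, cfg)
        swapped = groups.map({"g1": "g2", "g2": "g1"})
        tab2 = sam_statistic(m, swapped, cfg)
        assert np.allclose(tab["d"].to_numpy(), -tab2["d"].to_numpy())
        assert np.allclose(tab["q"].to_numpy(), tab2["q"].to_numpy())

    def test_fixed_seed_is_bit_reproducible(self):
        m, groups = two_group_matrix(seed=5, n1=6, n2=6)
        cfg = SamConfig(n_permutations=100, seed=17)
        a = sam_statistic(m, groups, cfg)
        b = sam_statistic(m, groups, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_exhaustive_enumeration_when_few_permutations(self):
        m, groups = two_group_matrix(n1=3, n2=3, seed=6)
        # C(6,3)=20 distinct splits < 1000 requested: all are used, and the
        # result no longer depends on the seed
        a = sam_statistic(m, groups, SamConfig(n_permutations=1000, seed=1))
        b = sam_statistic(m, groups, SamConfig(n_permutations=1000, seed=999))
        pd.testing.assert_frame_equal(a, b)
        assert (a["q"] >= 0).all() and (a["q"] <= 1).all()

    def test_auto_s0_nonnegative_and_damps_small_s(self):
        m, groups = two_group_matrix(n_genes=500, n1=8, n2=8, seed=7)
        tab = sam_statistic(m, groups, SamConfig(s0="auto", n_permutations=20, seed=1))
        assert tab.attrs["s0"] >= 0.0
        # with s0 > 0, |d| never exceeds |t|
        assert (np.abs(tab["d"]) <= np.abs(tab["t"]) + 1e-12).all()

    def test_q_monotone_in_abs_d(self):
        m, groups = two_group_matrix(n_genes=100, seed=8, shift_first=4.0)
        tab = sam_statistic(m, groups, SamConfig(n_permutations=100, seed=3))
        s = tab.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(s["q"].to_numpy()) >= -1e-12).all()

    def test_one_group_empty_errors(self):
        m, _ = two_group_matrix()
        groups = pd.Series({c: "g1" for c in m.cell_ids})
        with pytest.raises(ValueError):
            sam_statistic(m, groups)


class TestWelch:
    def test_type_one_error_controlled_under_null(self):
        rng = np.random.default_rng(100)
        X = rng.normal(size=(1000, 20))
        cells = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        m = make_matrix(X, cells=cells)
        groups = pd.Series({c: c[0] for c in cells})
        tab = welch_tests(m, groups)
        frac = float((tab["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_identical_group_values_give_t0_p1(self):
        X = np.vstack([np.array([1, 2, 3, 1, 2, 3], dtype=float),
                       np.array([0, 1, 2, 3, 4, 5], dtype=float)])
        cells = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        m = make_matrix(X, cells=cells)
        groups = pd.Series({c: c[0] for c in cells})
        tab = welch_tests(m, groups)
        assert tab.at["G0", "t"] == 0.0 and tab.at["G0", "p"] == 1.0

    def test_planted_signal_gets_smallest_q(self):
        m, groups = two_group_matrix(n_genes=200, n1=6, n2=6, seed=9, shift_first=5.0)
        tab = welch_tests(m, groups)
        assert tab["q"].idxmin() == "G0"

    def test_matches_scipy_welch(self):
        m, groups = two_group_matrix(seed=10)
        tab = welch_tests(m, groups)
        t, p = stats.ttest_ind(m.values.iloc[:, :4], m.values.iloc[:, 4:],
                               axis=1, equal_var=False)
        assert np.allclose(tab["t"].to_numpy(), t)
        assert np.allclose(tab["p"].to_numpy(), p)


class TestTopBottomK:
    def test_partition_and_sizes(self):
        tab = pd.DataFrame({"d": np.linspace(-3, 3, 20)},
                           index=pd.Index([f"G{i:02d}" for i in range(20)], name="gene"))
        up, down = top_bottom_k(tab, k=5)
        assert len(up) == len(down) == 5
        assert not (up.genes & down.genes)

    def test_half_split_covers_all_genes(self):
        tab = pd.DataFrame({"d": np.arange(10, dtype=float)},
                           index=pd.Index([f"G{i}" for i in range(10)], name="gene"))
        up, down = top_bottom_k(tab, k=5)
        assert up.genes | down.genes == set(tab.index)

    def test_tie_at_boundary_is_stable(self):
        d = np.array([3.0, 2.0, 1.0, 1.0, 1.0, -1.0, -2.0, -3.0])
        tab = pd.DataFrame({"d": d}, index=pd.Index(list("ABCDEFGH"), name="gene"))
        first = top_bottom_k(tab, k=3)
        second = top_bottom_k(tab.iloc[::-1], k=3)
        assert first[0].genes == second[0].genes == {"A", "B", "C"}
        assert first[1].genes == second[1].genes

    def test_too_few_genes_errors(self):
        tab = pd.DataFrame({"d": [1.0, -1.0]}, index=pd.Index(["A", "B"], name="gene"))
        with pytest.raises(ValueError, match="top/bottom"):
            top_bottom_k(tab, k=2)


class TestTopVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 8))
        X[2] = 5.0
        m = make_matrix(X)
        assert "G2" not in top_variable_genes(m, k=5)

    def test_matches_brute_force_iqr_order(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, [[1], [5], [0.2], [3], [2]], size=(5, 8))
        m = make_matrix(X)
        iqrs = {g: np.quantile(X[i], 0.75) - np.quantile(X[i], 0.25)
                for i, g in enumerate(m.probe_ids)}
        expected = sorted(iqrs, key=lambda g: -iqrs[g])
        assert top_variable_genes(m, k=5) == expected

    def test_k_equal_gene_count_returns_all(self, toy_matrix):
        assert set(top_variable_genes(toy_matrix, k=10)) == set(toy_matrix.probe_ids)

    def test_k_too_large_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            top_variable_genes(toy_matrix, k=11)
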