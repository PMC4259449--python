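import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dtcsig import (filter_cells, filter_probes, loess_normalize_within,
                    quantile_normalize_across)
from dtcsig.simulate import SimConfig, simulate

from conftest import make_matrix


def quantile_oracle(X):
    """Classic sort / row-mean / unsort quantile normalization (complete data)."""
    order = np.argsort(X, axis=0)
    ranks = np.argsort(order, axis=0)
    target = np.sort(X, axis=0).mean(axis=1)
    return target[ranks]


class TestLoess:
    def _ma(self, M, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.lognormal(np.log(1000), 0.5, size=np.shape(M))
        return make_matrix(M, intensities=A)

    def test_all_zero_m_stays_zero(self):
        m = self._ma(np.zeros((50, 3)))
        out = loess_normalize_within(m)
        assert np.allclose(out.values.to_numpy(), 0.0, atol=1e-9)

    def test_constant_m_becomes_zero_residual(self):
        m = self._ma(np.full((50, 2), 1.7))
        out = loess_normalize_within(m)
        assert np.all(np.abs(out.values.to_numpy()) < 1e-6)

    def test_intensity_trend_removed(self):
        rng = np.random.default_rng(11)
        A = rng.lognormal(np.log(1000), 0.8, size=(500, 1))
        M = 0.1 * np.log2(A) + rng.normal(0, 0.01, size=A.shape)
        out = loess_normalize_within(make_matrix(M, intensities=A))
        assert np.mean(np.abs(out.values.to_numpy())) < 0.05

    def test_too_few_points_passes_through_with_warning(self, caplog):
        m = self._ma(np.ones((5, 2)))
        with caplog.at_level("WARNING"):
            out = loess_normalize_within(m)
        assert "loess skipped" in caplog.text
        assert np.allclose(out.values.to_numpy(), 1.0)

    def test_missing_entries_stay_missing_and_dims_unchanged(self):
        M = np.random.default_rng(1).normal(size=(60, 3))
        M[4, 1] = np.nan
        m = self._ma(M)
        out = loess_normalize_within(m)
        assert out.values.shape == m.values.shape
        assert np.isnan(out.values.iloc[4, 1])
        assert out.values.isna().sum().sum() == 1


class TestQuantileNormalize:
    def test_identical_cells_unchanged(self):
        col = np.random.default_rng(2).normal(size=20)
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize_across(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_permuted_cells_share_sorted_values(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=30)
        m = make_matrix(np.column_stack([col, rng.permutation(col)]))
        out = quantile_normalize_across(m).values.to_numpy()
        assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))

    def test_three_by_three_matches_rank_mean_oracle(self):
        X = np.array([[5.0, 4.0, 3.0], [2.0, 1.0, 4.0], [3.0, 4.5, 6.0]])
        out = quantile_normalize_across(make_matrix(X)).values.to_numpy()
        assert np.allclose(out, quantile_oracle(X), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.float64, (6, 4), elements=st.floats(-10, 10),
                  unique=True))
    def test_idempotent_and_matches_oracle_on_complete_data(self, X):
        once = quantile_normalize_across(make_matrix(X)).values.to_numpy()
        twice = quantile_normalize_across(make_matrix(once)).values.to_numpy()
        assert np.allclose(once, twice, atol=1e-12)
        assert np.allclose(once, quantile_oracle(X), atol=1e-12)

    def test_ranks_preserved_with_missing_values(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        X[rng.random(X.shape) < 0.2] = np.nan
        out = quantile_normalize_across(make_matrix(X)).values.to_numpy()
        for j in range(5):
            ok = np.isfinite(X[:, j])
            assert np.array_equal(np.argsort(X[ok, j]), np.argsort(out[ok, j]))
        assert np.array_equal(np.isnan(X), np.isnan(out))


class TestFilterCells:
    def _with_missing(self, frac_by_cell, n_probes=100):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n_probes, len(frac_by_cell)))
        for j, f in enumerate(frac_by_cell):
            k = int(round(f * n_probes))
            X[:k, j] = np.nan
        A = np.full_like(X, 1000.0)
        return make_matrix(X, intensities=A)

    def test_thirty_percent_missing_removed(self):
        m = self._with_missing([0.30, 0.0])
        out, rep = filter_cells(m, min_median_signal=0)
        assert out.n_cells == 1 and rep.cells_removed_missing == 1

    def test_exactly_25_percent_retained(self):
        # the rule is strictly "more than" 25%
        m = self._with_missing([0.25, 0.0])
        out, rep = filter_cells(m, min_median_signal=0)
        assert out.n_cells == 2 and rep.cells_removed_missing == 0

    def test_planted_qc_failures_recovered(self):
        m, records, sets, truth = simulate(
            SimConfig(n_patients_ned=1, n_patients_adv=1, cells_per_patient=5,
                      n_genes=200, n_qc_fail_cells=2, seed=9))
        out, rep = filter_cells(m, min_median_signal=0)
        assert out.n_cells == 8
        assert set(rep.removed_cells) == set(truth.qc_fail_cells)

    def test_all_removed_errors(self):
        m = self._with_missing([0.5, 0.6])
        with pytest.raises(ValueError, match="no cells survive"):
            filter_cells(m, min_median_signal=0)

    def test_report_reconciles_with_shapes(self):
        m = self._with_missing([0.4, 0.0, 0.1, 0.5])
        out, rep = filter_cells(m, min_median_signal=0)
        assert rep.cells_in == 4
        assert rep.cells_retained == out.n_cells
        assert rep.cells_in - rep.cells_removed_missing - rep.cells_removed_signal == out.n_cells

    def test_low_signal_cells_removed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        A = np.full_like(X, 1000.0)
        A[:, 2] = 10.0
        out, rep = filter_cells(make_matrix(X, intensities=A), min_median_signal=300)
        assert out.n_cells == 2 and rep.cells_removed_signal == 1


class TestFilterProbes:
    def test_mean_299_removed_mean_300_retained(self):
        X = np.zeros((3, 4))
        A = np.vstack([np.full(4, 299.0), np.full(4, 300.0), np.full(4, 500.0)])
        out, rep = filter_probes(make_matrix(X, intensities=A))
        assert out.n_probes == 2
        assert rep.probes_removed_low_intensity == 1
        assert "G0" in rep.removed_probes

    def test_planted_low_intensity_fraction_removed(self):
        # 100 genes; the generator plants low-intensity probes only among
        # background genes, everything else is kept above the floor
        cfg = SimConfig(n_patients_ned=1, n_patients_adv=1, cells_per_patient=5,
                        n_genes=163, frac_low_intensity=0.3, seed=12)
        m, *_ , truth = simulate(cfg)
        out, rep = filter_probes(m)
        assert rep.probes_removed_low_intensity == len(truth.low_intensity_genes)
        assert out.n_probes == 163 - len(truth.low_intensity_genes)

    def test_mean_uses_nonmissing_entries_and_values_untouched(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        A = np.array([[100.0, 500.0], [400.0, 400.0]])
        # probe G0 mean over non-missing entries handled consistently
        out, rep = filter_probes(make_matrix(X, intensities=A), min_mean_intensity=300)
        assert np.array_equal(out.values.to_numpy(),
                              np.array([[1.0, np.nan], [2.0, 3.0]]), equal_nan=True)

    def test_all_removed_errors(self):
        X = np.zeros((2, 2))
        A = np.full((2, 2), 10.0)
        with pytest.raises(ValueError, match="no probes"):
            filter_probes(make_matrix(X, intensities=A))
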