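"""Differential expression: filtering, TMM, dispersion, exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regionsift as rs
from regionsift.de import DEParams, run_de
from conftest import GROUPS, SAMPLES, nb_matrix


def frame(arr, index=None):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(arr, columns=SAMPLES[: arr.shape[1]], index=index)


class TestFilterLowCounts:
    def test_row_below_threshold_dropped(self):
        x = frame([[0, 0, 1, 0, 0, 0], [2, 2, 2, 2, 2, 2]])
        kept = rs.filter_low_counts(x, min_count=1, min_samples=2)
        assert list(kept.index) == [1]

    def test_zero_min_count_is_identity(self):
        x = frame(np.zeros((3, 6), dtype=int))
        assert rs.filter_low_counts(x, min_count=0, min_samples=6).equals(x)

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(0)
        x = frame(rng.integers(0, 5, (50, 6)))
        kept = rs.filter_low_counts(x, min_count=2, min_samples=3)
        expected = [i for i in x.index if (x.loc[i] >= 2).sum() >= 3]
        assert list(kept.index) == expected


class TestTMM:
    def test_identical_samples_unit_factors(self):
        x = frame(np.tile([[5], [10], [2], [7]], (1, 6)))
        assert rs.tmm_factors(x).tolist() == pytest.approx([1.0] * 6)

    def test_pure_library_size_difference_unit_factors(self):
        # doubling every count changes the library size, not composition:
        # all M-values vs the reference are 0, so factors stay 1
        base = np.array([[5], [10], [2], [7], [30]])
        x = pd.DataFrame(np.hstack([base, 2 * base, 4 * base]),
                         columns=["a", "b", "c"])
        assert rs.tmm_factors(x).tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_log_factors_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = frame(rng.integers(0, 200, (300, 8)))
        assert np.log(rs.tmm_factors(x)).sum() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        x = frame([[1, 0], [2, 0], [3, 0]])
        with pytest.raises(ValueError, match="s1"):
            rs.tmm_factors(x)


class TestCommonDispersion:
    def test_poisson_matrix_near_zero(self):
        rng = np.random.default_rng(2)
        x = frame(nb_matrix(rng, 100, 0.0, (2000, 12)))
        assert rs.estimate_common_dispersion(x, GROUPS) < 0.02

    def test_nb_phi_recovered(self):
        rng = np.random.default_rng(3)
        x = frame(nb_matrix(rng, 100, 0.4, (2000, 12)))
        assert 0.25 <= rs.estimate_common_dispersion(x, GROUPS) <= 0.55

    def test_constant_counts_zero(self):
        x = frame(np.full((10, 12), 7))
        assert rs.estimate_common_dispersion(x, GROUPS) == 0.0

    def test_single_sample_group_rejected(self):
        x = frame(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError, match="2 samples"):
            rs.estimate_common_dispersion(x, [1, 1, 2])


class TestExactTest:
    def equal_lib_matrix(self, rng, shape):
        """Random counts padded so every column sum is identical."""
        base = rng.integers(0, 20, shape)
        pad = base.sum(axis=0).max() - base.sum(axis=0)
        return frame(np.vstack([base, pad]))

    def test_reduces_to_binomial_at_zero_dispersion(self):
        # phi = 0 and equal effective library sizes: the conditional NB test
        # is the exact two-sided binomial test of k vs n-k with p = n1/(n1+n2)
        rng = np.random.default_rng(4)
        x = self.equal_lib_matrix(rng, (50, 12))
        unit = pd.Series(1.0, index=x.columns)
        res = rs.exact_test(x, GROUPS, factors=unit, dispersion=0.0)
        for rid in x.index:
            s1 = int(x.loc[rid][:6].sum())
            t = s1 + int(x.loc[rid][6:].sum())
            pmf = stats.binom.pmf(np.arange(t + 1), t, 0.5)
            expected = min(1.0, pmf[pmf <= pmf[s1] * (1 + 1e-8)].sum())
            assert res.at[rid, "PValue"] == pytest.approx(expected, abs=1e-9)

    def test_group_swap_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(5)
        x = self.equal_lib_matrix(rng, (20, 12))
        unit = pd.Series(1.0, index=x.columns)
        a = rs.exact_test(x, GROUPS, factors=unit, dispersion=0.1)
        b = rs.exact_test(x, [3 - g for g in GROUPS], factors=unit, dispersion=0.1)
        assert np.allclose(a["logFC"], -b["logFC"])
        assert np.allclose(a["PValue"], b["PValue"])

    def test_flat_row_null(self):
        x = frame([[5] * 12])
        unit = pd.Series(1.0, index=x.columns)
        res = rs.exact_test(x, GROUPS, factors=unit, dispersion=0.1)
        assert res.iloc[0]["logFC"] == 0.0
        assert res.iloc[0]["PValue"] == pytest.approx(1.0)

    def test_invariant_to_common_library_scaling(self):
        # multiplying every effective library size by a constant (here via a
        # common scaling factor) leaves pseudo-counts and p-values unchanged
        rng = np.random.default_rng(6)
        x = frame(rng.integers(1, 50, (20, 12)))
        unit = pd.Series(1.0, index=x.columns)
        a = rs.exact_test(x, GROUPS, factors=unit, dispersion=0.05)
        b = rs.exact_test(x, GROUPS, factors=unit * 3.0, dispersion=0.05)
        assert np.allclose(a["PValue"], b["PValue"])
        assert np.allclose(a["logFC"], b["logFC"])

    def test_negative_counts_rejected(self):
        x = frame([[1, -1, 2, 2, 2, 2]])
        with pytest.raises(ValueError, match="negative"):
            rs.exact_test(x, [1, 1, 1, 2, 2, 2])


class TestBH:
    def test_step_up_hand_example(self):
        # m=3: adjusted = min over j>=i of p_(j)*m/j = [0.03, 0.03, 0.03]
        assert rs.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert rs.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert rs.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rs.bh_adjust([0.5, 1.5])

    def test_monotone_when_a_p_decreases(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=20)
        q = rs.bh_adjust(p)
        p2 = p.copy()
        p2[3] = p2[3] / 2
        q2 = rs.bh_adjust(p2)
        assert (q2 <= q + 1e-12).all()


class TestPipelineCalibration:
    def test_type_one_error_controlled(self):
        """Null NB simulation (phi=0.1, n=6+6): raw p < 0.05 for ~5 % of rows."""
        rng = np.random.default_rng(8)
        x = frame(nb_matrix(rng, 100, 0.1, (2000, 12)))
        res = run_de(x, GROUPS, DEParams())
        frac = (res["PValue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_two_fold_effect_recovered(self):
        """Planted symmetric 2-fold rows at baseline 200 recover logFC ~ +-1."""
        rng = np.random.default_rng(9)
        up = np.column_stack([nb_matrix(rng, 200, 0.1, (200, 6)),
                              nb_matrix(rng, 400, 0.1, (200, 6))])
        down = np.column_stack([nb_matrix(rng, 200, 0.1, (200, 6)),
                                nb_matrix(rng, 100, 0.1, (200, 6))])
        null = np.column_stack([nb_matrix(rng, 200, 0.1, (600, 6)),
                                nb_matrix(rng, 200, 0.1, (600, 6))])
        x = frame(np.vstack([up, down, null]))
        res = run_de(x, GROUPS, DEParams())
        assert res["logFC"][:200].mean() == pytest.approx(1.0, abs=0.2)
        assert res["logFC"][200:400].mean() == pytest.approx(-1.0, abs=0.2)
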