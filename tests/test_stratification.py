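"""Quantile binning, per-bin means, min-max rows, Kruskal-Wallis testing."""

import numpy as np
import pandas as pd
import pytest

from micromarkers import (AbundanceProfile, binned_means,
                          kruskal_wallis_per_feature, minmax_rows,
                          quantile_bins, stratify)


class TestQuantileBins:
    def test_linear_interpolation_boundaries_on_1_to_8(self):
        boundaries, _ = quantile_bins(np.arange(1.0, 9.0))
        np.testing.assert_allclose(boundaries, [2.75, 4.5, 6.25])

    def test_boundary_value_assigned_to_upper_bin(self):
        # for 9 values the quartile boundaries are (3, 4.5, 6); the sample
        # at exactly 4.5 falls in Q3 under the half-open [b_{k-1}, b_k)
        # convention, and the ones at 3 and 6 in Q2 and Q4
        values = np.array([1.0, 2.0, 3.0, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0])
        boundaries, assignments = quantile_bins(values)
        np.testing.assert_allclose(boundaries, [3.0, 4.5, 6.0])
        assert assignments[values == 4.5][0] == 2  # zero-based Q3
        assert assignments[values == 3.0][0] == 1
        assert assignments[values == 6.0][0] == 3

    def test_four_distinct_values_one_per_bin(self):
        _, assignments = quantile_bins(np.array([1.0, 2.0, 3.0, 4.0]))
        assert sorted(assignments.tolist()) == [0, 1, 2, 3]

    def test_every_sample_assigned_exactly_once(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=101)
        _, assignments = quantile_bins(values)
        assert assignments.size == 101
        assert set(assignments.tolist()) == {0, 1, 2, 3}

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins(np.full(10, 2.0))

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins(np.arange(8.0), probs=(0.5, 0.25))


class TestBinnedMeans:
    def make_profile(self, values):
        values = np.asarray(values, dtype=float)
        return AbundanceProfile([f"s{i}" for i in range(values.shape[0])],
                                [f"f{j}" for j in range(values.shape[1])],
                                values)

    def test_one_sample_per_bin_returns_those_rows(self):
        prof = self.make_profile([[0.1, 0.9], [0.4, 0.6]])
        means = binned_means(prof, [0, 1])
        np.testing.assert_allclose(means["Q1"], [0.1, 0.9])
        np.testing.assert_allclose(means["Q2"], [0.4, 0.6])

    def test_mean_of_two_samples(self):
        prof = self.make_profile([[0.1, 0.9], [0.3, 0.7]])
        means = binned_means(prof, [0, 0])
        np.testing.assert_allclose(means["Q1"], [0.2, 0.8])

    def test_empty_bin_named_in_error(self):
        prof = self.make_profile([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="Q2"):
            binned_means(prof, [0, 2])


class TestMinmaxRows:
    def test_affine_row_maps_to_unit_interval(self):
        m = pd.DataFrame([[2.0, 4.0, 6.0, 8.0]])
        np.testing.assert_allclose(minmax_rows(m).to_numpy()[0],
                                   [0.0, 1 / 3, 2 / 3, 1.0])

    def test_constant_row_maps_to_zeros(self):
        m = pd.DataFrame([[0.2, 0.2, 0.2]])
        np.testing.assert_array_equal(minmax_rows(m).to_numpy()[0], 0.0)

    def test_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.random((4, 5)))
        a = minmax_rows(m)
        b = minmax_rows(3.7 * m + 11.0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_nonconstant_rows_attain_zero_and_one(self):
        rng = np.random.default_rng(6)
        out = minmax_rows(pd.DataFrame(rng.random((6, 4)))).to_numpy()
        np.testing.assert_allclose(out.min(axis=1), 0.0)
        np.testing.assert_allclose(out.max(axis=1), 1.0)


class TestKruskalWallis:
    def make_profile(self, column):
        column = np.asarray(column, dtype=float)[:, None]
        values = np.c_[column, 1.0 - column]
        return AbundanceProfile([f"s{i}" for i in range(len(column))],
                                ["f0", "f1"], values)

    def test_hand_worked_h_statistic(self):
        # groups {1,2} vs {3,4}: H = 12/20 * (3^2/2 + 7^2/2) - 15 = 2.4
        prof = self.make_profile([0.1, 0.2, 0.3, 0.4])
        out = kruskal_wallis_per_feature(prof, [1, 1, 0, 0])
        assert out.loc["f0", "H"] == pytest.approx(2.4)

    def test_constant_feature_h_zero_not_significant(self):
        values = np.c_[np.full(8, 0.5), np.linspace(0.1, 0.8, 8)]
        prof = AbundanceProfile([f"s{i}" for i in range(8)], ["c", "v"],
                                values)
        out = kruskal_wallis_per_feature(prof, [0, 1] * 4)
        assert out.loc["c", "H"] == 0.0
        assert out.loc["c", "significance"] == "not-significant"

    def test_direction_classes(self):
        case_high = np.r_[np.linspace(0.6, 0.9, 10), np.linspace(0.1, 0.4, 10)]
        prof = self.make_profile(case_high)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        out = kruskal_wallis_per_feature(prof, labels)
        assert out.loc["f0", "significance"] == "higher-in-case"
        assert out.loc["f1", "significance"] == "higher-in-control"

    def test_small_group_rejected(self):
        prof = self.make_profile([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            kruskal_wallis_per_feature(prof, [1, 0, 0, 0])

    def test_benjamini_hochberg_option_is_more_conservative(self):
        rng = np.random.default_rng(9)
        values = rng.random((40, 30))
        values[:20, 0] += 0.8   # one truly shifted feature among nulls
        prof = AbundanceProfile([f"s{i}" for i in range(40)],
                                [f"f{j}" for j in range(30)], values)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        raw = kruskal_wallis_per_feature(prof, labels)
        bh = kruskal_wallis_per_feature(prof, labels,
                                        correction="benjamini-hochberg")
        assert (bh["p_adjusted"] >= bh["p"] - 1e-15).all()
        n_sig_raw = (raw["significance"] != "not-significant").sum()
        n_sig_bh = (bh["significance"] != "not-significant").sum()
        assert n_sig_bh <= n_sig_raw
        assert bh.loc["f0", "significance"] == "higher-in-case"

    def test_p_monotone_in_rank_separation(self):
        """With fixed group sizes and no ties, stronger rank separation
        gives a smaller p-value."""
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        base = np.linspace(0.1, 0.9, 12)
        pvals = []
        for n_exchanged in (0, 1, 2):   # cross-group swaps weaken separation
            values = base.copy()        # cases initially hold the top ranks
            case_vals = values[6:].copy()
            ctrl_vals = values[:6].copy()
            for s in range(n_exchanged):
                case_vals[s], ctrl_vals[s] = ctrl_vals[s], case_vals[s]
            prof = self.make_profile(np.r_[case_vals, ctrl_vals])
            out = kruskal_wallis_per_feature(prof, labels)
            pvals.append(out.loc["f0", "p"])
        assert pvals[0] < pvals[1] < pvals[2]


def test_full_stratification_pipeline(small_cohort):
    profile, metadata, _ = small_cohort
    fbg = np.array([m.covariates["fbg"] for m in metadata])
    labels = np.array([m.label for m in metadata])
    strat = stratify(profile, fbg, labels)
    assert strat.matrix.shape == (profile.n_features, 4)
    vals = strat.matrix.to_numpy()
    assert (vals >= 0).all() and (vals <= 1).all()
    assert list(strat.matrix.columns) == ["Q1", "Q2", "Q3", "Q4"]
    assert len(strat.boundaries) == 3
    assert set(strat.significance["significance"]) <= {
        "higher-in-case", "higher-in-control", "not-significant"}
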