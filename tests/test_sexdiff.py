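"""Group means, aggregation, the 95% band and the summary tables."""

import numpy as np
import pandas as pd
import pytest

from sexscan.core import GenomeIndex, Sample, make_window_grid
from sexscan.errors import ConfigError
from sexscan.sexdiff import (
    aggregate_windows,
    confidence_band,
    flag_outlier_windows,
    per_chromosome_summary,
    per_sample_profiles,
    per_scaffold_summary,
    sex_difference,
    sex_group_means,
)


def _samples(n_het=2, n_hom=2):
    out = []
    for i in range(n_het):
        out.append(Sample(f"H{i}", "male"))
        out[-1].role = "heterogametic"
    for i in range(n_hom):
        out.append(Sample(f"G{i}", "female"))
        out[-1].role = "homogametic"
    return out


class TestGroupMeans:
    def test_mean_of_two(self):
        vals = pd.DataFrame({"H0": [0.4], "H1": [0.6], "G0": [1.0], "G1": [1.0]})
        m = sex_group_means(vals, _samples())
        assert m.loc[0, "heterogametic"] == pytest.approx(0.5)
        assert m.loc[0, "diff"] == pytest.approx(-0.5)

    def test_single_sample_roles_pass_through(self):
        vals = pd.DataFrame({"H0": [0.7, 0.2], "G0": [1.0, 0.9]})
        m = sex_group_means(vals, _samples(1, 1))
        np.testing.assert_allclose(m["heterogametic"], vals["H0"])
        np.testing.assert_allclose(m["homogametic"], vals["G0"])

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.random((50, 4)), columns=["H0", "H1", "G0", "G1"])
        m = sex_group_means(vals, _samples())
        np.testing.assert_allclose(m["heterogametic"], (vals["H0"] + vals["H1"]) / 2)
        np.testing.assert_allclose(
            m["diff"], (vals["H0"] + vals["H1"]) / 2 - (vals["G0"] + vals["G1"]) / 2
        )

    def test_antisymmetry_under_role_swap(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.random((30, 4)), columns=["H0", "H1", "G0", "G1"])
        m1 = sex_group_means(vals, _samples())
        swapped = _samples()
        for s in swapped:
            s.role = "homogametic" if s.role == "heterogametic" else "heterogametic"
        m2 = sex_group_means(vals, swapped)
        np.testing.assert_allclose(sex_difference(m1), -sex_difference(m2))

    def test_signed_patterns(self):
        # degenerate region: heterogametic coverage 0.5 vs 1.0 -> diff -0.5
        vals = pd.DataFrame({"H0": [0.5], "G0": [1.0]})
        assert sex_group_means(vals, _samples(1, 1))["diff"].iloc[0] == pytest.approx(-0.5)
        # low differentiation: het excess in the heterogametic sex -> +0.003
        vals = pd.DataFrame({"H0": [0.004], "G0": [0.001]})
        assert sex_group_means(vals, _samples(1, 1))["diff"].iloc[0] == pytest.approx(0.003)


class TestAggregation:
    def setup_method(self):
        self.index = GenomeIndex([("c1", 1_000_000)])
        self.grid = make_window_grid(self.index, 5000)

    def test_constant_units(self):
        vals = pd.DataFrame({"v": np.ones(len(self.grid))})
        agg = aggregate_windows(vals, self.grid, self.index, 1_000_000, 5000)
        assert len(agg) == 1
        assert agg.loc[0, "v"] == pytest.approx(1.0)
        assert agg.loc[0, "n"] == 200

    def test_all_masked_is_missing(self):
        vals = pd.DataFrame({"v": np.ones(len(self.grid))})
        masked = pd.Series(True, index=self.grid.index)
        masked.iloc[:3] = False  # 3 < min_contributing
        agg = aggregate_windows(vals, self.grid, self.index, 1_000_000, 5000, masked=masked)
        assert np.isnan(agg.loc[0, "v"])
        assert agg.loc[0, "n"] == 3

    def test_matches_midpoint_binning_oracle(self):
        rng = np.random.default_rng(2)
        index = GenomeIndex([("c1", 230_000), ("c2", 170_000)])
        grid = make_window_grid(index, 5000)
        vals = pd.DataFrame({"v": rng.random(len(grid))})
        masked = pd.Series(rng.random(len(grid)) < 0.2, index=grid.index)
        rw = 50_000
        agg = aggregate_windows(vals, grid, index, rw, 5000, masked=masked)
        for _, row in agg.iterrows():
            sel = (
                (grid["scaffold"] == row["scaffold"])
                & (((grid["start"] + grid["end"]) // 2) >= row["start"])
                & (((grid["start"] + grid["end"]) // 2) < row["end"])
                & ~masked
                & ~grid["short"]
            )
            exp = vals.loc[sel, "v"]
            if len(exp) < 5:
                assert np.isnan(row["v"])
            else:
                assert row["v"] == pytest.approx(exp.mean())
            assert row["n"] == sel.sum()

    def test_weighted_mean_identity(self):
        """Genome-wide mean from aggregates equals the unit-window mean."""
        rng = np.random.default_rng(3)
        vals = pd.DataFrame({"v": rng.random(len(self.grid))})
        agg = aggregate_windows(vals, self.grid, self.index, 50_000, 5000)
        lhs = (agg["v"] * agg["n"]).sum() / agg["n"].sum()
        assert lhs == pytest.approx(vals["v"].mean())

    def test_bad_multiple_rejected(self):
        vals = pd.DataFrame({"v": np.ones(len(self.grid))})
        with pytest.raises(ConfigError):
            aggregate_windows(vals, self.grid, self.index, 7001, 5000)


class TestBand:
    def test_constant_diffs_degenerate_band(self):
        d = pd.Series(np.full(100, 0.25))
        b = confidence_band(d, "m")
        assert b.low == b.high == pytest.approx(0.25)
        flags = flag_outlier_windows(d, b)
        assert (flags == "none").all()

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(4)
        d = pd.Series(rng.standard_normal(20_000))
        b = confidence_band(d, "m")
        assert b.low == pytest.approx(-1.96, abs=0.08)
        assert b.high == pytest.approx(1.96, abs=0.08)
        frac = (flag_outlier_windows(d, b) != "none").mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_stddev_method(self):
        rng = np.random.default_rng(5)
        d = pd.Series(rng.standard_normal(20_000))
        b = confidence_band(d, "m", method="stddev")
        assert b.low == pytest.approx(-1.96, abs=0.08)

    def test_too_few_windows_omits_band(self):
        b = confidence_band(pd.Series(np.arange(10.0)), "m")
        assert b is None
        flags = flag_outlier_windows(pd.Series(np.arange(10.0)), b)
        assert (flags == "none").all()

    def test_injected_block_flagged_low(self):
        rng = np.random.default_rng(6)
        d = pd.Series(np.r_[rng.normal(0, 0.01, 98), [-0.5, -0.5]])
        b = confidence_band(d, "m")
        flags = flag_outlier_windows(d, b)
        assert (flags.iloc[-2:] == "low").all()

    def test_balanced_null_role_permutation_keeps_rate(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(1, 0.05, (400, 4)), columns=["H0", "H1", "G0", "G1"])
        for samples in (_samples(), _samples()):
            m = sex_group_means(vals, samples)
            b = confidence_band(m["diff"], "m")
            frac = (flag_outlier_windows(m["diff"], b) != "none").mean()
            assert 0.02 <= frac <= 0.10
        # permuted labels: swap one pair
        perm = _samples()
        perm[0].role, perm[2].role = "homogametic", "heterogametic"
        m = sex_group_means(vals, perm)
        b = confidence_band(m["diff"], "m")
        frac = (flag_outlier_windows(m["diff"], b) != "none").mean()
        assert 0.02 <= frac <= 0.10


class TestSummaries:
    def test_single_scaffold_equals_genome_mean(self):
        index = GenomeIndex([("c1", 100_000)])
        grid = make_window_grid(index, 5000)
        rng = np.random.default_rng(8)
        d = pd.Series(rng.random(len(grid)))
        s = per_scaffold_summary({"m": d}, grid, index)
        assert s.loc["c1", "m"] == pytest.approx(d.mean())
        assert s.loc["c1", "length"] == 100_000

    def test_fully_masked_scaffold_excluded(self):
        index = GenomeIndex([("c1", 50_000), ("c2", 50_000)])
        grid = make_window_grid(index, 5000)
        masked = pd.Series(grid["scaffold"] == "c2", index=grid.index)
        d = pd.Series(np.ones(len(grid)))
        s = per_scaffold_summary({"m": d}, grid, index, masked=masked)
        assert list(s.index) == ["c1"]

    def test_matches_groupby_brute_force(self):
        index = GenomeIndex([("a", 60_000), ("b", 45_000), ("c", 30_000)])
        grid = make_window_grid(index, 5000)
        rng = np.random.default_rng(9)
        d = pd.Series(rng.standard_normal(len(grid)))
        masked = pd.Series(rng.random(len(grid)) < 0.1, index=grid.index)
        s = per_scaffold_summary({"m": d}, grid, index, masked=masked)
        for name in s.index:
            sel = (grid["scaffold"] == name) & ~masked & ~grid["short"]
            assert s.loc[name, "m"] == pytest.approx(d[sel].mean())

    def test_chromosome_summary_sd(self):
        agg = {
            "m": pd.DataFrame(
                {
                    "scaffold": ["a"] * 3 + ["b"],
                    "diff": [0.2, 0.2, 0.2, 0.5],
                }
            )
        }
        summary, medians = per_chromosome_summary(agg)
        a = summary[summary["scaffold"] == "a"].iloc[0]
        b = summary[summary["scaffold"] == "b"].iloc[0]
        assert a["sd"] == 0.0 and a["n"] == 3  # constant -> SD 0
        assert b["sd"] == 0.0 and b["n"] == 1  # single window -> SD reported 0
        assert medians["m"] == pytest.approx(0.2)

    def test_chromosome_summary_matches_brute_force(self):
        rng = np.random.default_rng(10)
        agg = {
            "m": pd.DataFrame(
                {
                    "scaffold": rng.choice(["a", "b"], 60),
                    "diff": rng.standard_normal(60),
                }
            )
        }
        summary, _ = per_chromosome_summary(agg)
        for name in ("a", "b"):
            sel = agg["m"][agg["m"]["scaffold"] == name]["diff"]
            row = summary[summary["scaffold"] == name].iloc[0]
            assert row["mean"] == pytest.approx(sel.mean())
            assert row["sd"] == pytest.approx(sel.std(ddof=1))

    def test_identical_samples_identical_profiles(self):
        index = GenomeIndex([("c1", 200_000)])
        grid = make_window_grid(index, 5000)
        rng = np.random.default_rng(11)
        v = rng.random(len(grid))
        vals = {"m": pd.DataFrame({"s1": v, "s2": v.copy()})}
        prof = per_sample_profiles(vals, grid, index, 50_000, 5000)
        np.testing.assert_allclose(prof["m"]["s1"], prof["m"]["s2"])
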