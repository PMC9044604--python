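"""Read filtering, window depth, masking and normalization checks."""

import numpy as np
import pandas as pd
import pysam
import pytest

from sexscan.core import GenomeIndex, MismatchSetting, make_window_grid
from sexscan.coverage import (
    FilterStats,
    bam_window_coverage,
    mask_outlier_windows,
    normalize_coverage,
    passes_alignment_filter,
    window_coverage,
)
from sexscan.errors import DataError

from conftest import random_records, write_bam
from oracles import pileup_coverage

STRICT = MismatchSetting("0mm", 0)
INTER = MismatchSetting("2mm", 2)
UNB = MismatchSetting("unfiltered", None)


def _record(refs={"s1": 10000}, **kw):
    header = pysam.AlignmentHeader.from_references(list(refs), list(refs.values()))
    a = pysam.AlignedSegment(header)
    a.query_name = "r"
    a.reference_id = 0
    a.reference_start = kw.get("pos", 100)
    a.mapping_quality = kw.get("mapq", 60)
    a.cigarstring = kw.get("cigar", "100M")
    a.flag = kw.get("flag", 0)
    if kw.get("nm", 0) is not None:
        a.set_tag("NM", kw.get("nm", 0))
    return a


class TestAlignmentFilter:
    def test_clean_read_passes_strict(self):
        assert passes_alignment_filter(_record(nm=0), STRICT)

    def test_three_mismatches_fail_intermediate(self):
        assert not passes_alignment_filter(_record(nm=3), INTER)
        assert passes_alignment_filter(_record(nm=3), UNB)

    @pytest.mark.parametrize("flag", [0x4, 0x100, 0x800, 0x400])
    def test_flag_gates_apply_to_every_setting(self, flag):
        assert not passes_alignment_filter(_record(flag=flag), UNB)

    def test_mapq_floor(self):
        assert not passes_alignment_filter(_record(mapq=10), UNB)
        assert passes_alignment_filter(_record(mapq=20), UNB)

    def test_missing_nm_excluded_from_bounded_and_counted(self):
        stats = FilterStats()
        assert not passes_alignment_filter(_record(nm=None), STRICT, stats=stats)
        assert stats.missing_nm == 1
        assert passes_alignment_filter(_record(nm=None), UNB, stats=stats)

    def test_kept_counts_match_exhaustive_nm_scan(self, tmp_path):
        rng = np.random.default_rng(42)
        refs = {"s1": 50_000}
        recs = random_records(rng, refs, 1000)
        bam = write_bam(tmp_path / "nm.bam", refs, recs)
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        _, stats = bam_window_coverage(bam, index, grid, 5000, [STRICT, INTER, UNB])
        # oracle: plain scan over the record dicts
        def ok(r):
            return r["flag"] == 0 and r["mapq"] >= 20
        assert stats.kept["unfiltered"] == sum(ok(r) for r in recs)
        assert stats.kept["0mm"] == sum(ok(r) and r["nm"] == 0 for r in recs)
        assert stats.kept["2mm"] == sum(ok(r) and r["nm"] <= 2 for r in recs)


class TestWindowCoverage:
    def test_single_read_in_window(self, tmp_path):
        refs = {"s1": 5000}
        bam = write_bam(tmp_path / "one.bam", refs, [{"ref": "s1", "pos": 1000}])
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        depth, _ = bam_window_coverage(bam, index, grid, 5000, [UNB])
        assert depth["unfiltered"][0] == pytest.approx(100 / 5000)

    def test_no_reads_gives_zero(self, tmp_path):
        refs = {"s1": 10000}
        bam = write_bam(tmp_path / "none.bam", refs, [])
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        depth, _ = bam_window_coverage(bam, index, grid, 5000, [UNB])
        assert (depth["unfiltered"] == 0).all()

    def test_boundary_read_split_proportionally(self, tmp_path):
        refs = {"s1": 10000}
        bam = write_bam(tmp_path / "split.bam", refs, [{"ref": "s1", "pos": 4950}])
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        depth, _ = bam_window_coverage(bam, index, grid, 5000, [UNB])
        assert depth["unfiltered"][0] == pytest.approx(50 / 5000)
        assert depth["unfiltered"][1] == pytest.approx(50 / 5000)

    def test_deletions_do_not_add_depth(self, tmp_path):
        refs = {"s1": 5000}
        bam = write_bam(
            tmp_path / "del.bam", refs,
            [{"ref": "s1", "pos": 100, "cigar": "30M10D30M"}],
        )
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        depth, _ = bam_window_coverage(bam, index, grid, 5000, [UNB])
        assert depth["unfiltered"][0] == pytest.approx(60 / 5000)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_base_pileup_oracle(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        refs = {"s1": 23_000, "s2": 11_000}
        recs = random_records(rng, refs, 500)
        bam = write_bam(tmp_path / f"rand{seed}.bam", refs, recs)
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        for setting in (STRICT, INTER, UNB):
            depth, _ = bam_window_coverage(bam, index, grid, 5000, [setting])
            oracle = pileup_coverage(bam, index, 5000, setting.max_mismatches)
            got = depth[setting.label]
            exp = np.concatenate([oracle[n] for n, _ in index.scaffolds])
            np.testing.assert_allclose(got, exp, rtol=0, atol=1e-12)

    def test_scaffold_absent_from_grid_errors(self, tmp_path):
        refs = {"s1": 10000, "rogue": 10000}
        bam = write_bam(tmp_path / "rogue.bam", refs, [{"ref": "rogue", "pos": 0}])
        index = GenomeIndex([("s1", 10000)])
        grid = make_window_grid(index, 5000)
        with pytest.raises(DataError, match="rogue"):
            bam_window_coverage(bam, index, grid, 5000, [UNB])

    def test_filtered_stream_interface_agrees(self, tmp_path):
        rng = np.random.default_rng(7)
        refs = {"s1": 30_000}
        recs = random_records(rng, refs, 300)
        bam = write_bam(tmp_path / "stream.bam", refs, recs)
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        with pysam.AlignmentFile(bam) as bf:
            kept = [r for r in bf if passes_alignment_filter(r, UNB)]
            vals = window_coverage(kept, grid, index, 5000)
        depth, _ = bam_window_coverage(bam, index, grid, 5000, [UNB])
        np.testing.assert_allclose(vals, depth["unfiltered"], atol=1e-12)

    def test_depth_times_length_equals_kept_aligned_bases(self, tmp_path):
        rng = np.random.default_rng(3)
        refs = {"s1": 40_000}
        recs = random_records(rng, refs, 400)
        bam = write_bam(tmp_path / "bases.bam", refs, recs)
        index = GenomeIndex(list(refs.items()))
        grid = make_window_grid(index, 5000)
        depth, stats = bam_window_coverage(bam, index, grid, 5000, [UNB])
        total = float((depth["unfiltered"] * grid["length"].to_numpy()).sum())
        assert total == pytest.approx(stats.aligned_bases["unfiltered"])


class TestMasking:
    def test_uniform_depth_unmasked(self):
        t = pd.DataFrame({"a": [10.0] * 50})
        assert not mask_outlier_windows(t).any()

    def test_single_spike_masked(self):
        vals = [10.0] * 49 + [200.0]
        t = pd.DataFrame({"a": vals})
        m = mask_outlier_windows(t)
        assert m.sum() == 1 and bool(m.iloc[-1])

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "a": np.where(rng.random(1000) < 0.01, 500.0, rng.poisson(10, 1000)),
                "b": rng.poisson(12, 1000).astype(float),
            }
        )
        m = mask_outlier_windows(t, mask_factor=10)
        exp = np.zeros(1000, dtype=bool)
        for col in t.columns:
            med = np.median(t[col])
            for i in range(1000):
                if t[col].iloc[i] > 10 * med:
                    exp[i] = True
        np.testing.assert_array_equal(m.to_numpy(), exp)

    def test_all_masked_is_degenerate(self):
        t = pd.DataFrame({"a": [0.0, 0.0, 100.0]})
        # median 0 -> everything positive masked; all-masked must raise
        with pytest.raises(DataError):
            mask_outlier_windows(pd.DataFrame({"a": [1.0]}), mask_factor=0.5)


class TestNormalization:
    def test_uniform_becomes_one(self):
        t = pd.DataFrame({"a": [10.0] * 20})
        m = pd.Series(False, index=t.index)
        assert (normalize_coverage(t, m)["a"] == 1.0).all()

    def test_depth_invariance_between_samples(self):
        t = pd.DataFrame({"a": [10.0] * 20, "b": [20.0] * 20})
        m = pd.Series(False, index=t.index)
        out = normalize_coverage(t, m)
        assert ((out["a"] - out["b"]).abs() < 1e-12).all()

    def test_mean_is_one_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"a": rng.gamma(4, 2, 500)})
        m = pd.Series(rng.random(500) < 0.05)
        out = normalize_coverage(t, m)
        assert out.loc[~m, "a"].mean() == pytest.approx(1.0, abs=1e-9)
        out2 = normalize_coverage(t * 7.3, m)
        np.testing.assert_allclose(out["a"], out2["a"], rtol=1e-12)

    def test_zero_mean_names_sample(self):
        t = pd.DataFrame({"bad_sample": [0.0] * 10, "ok": [1.0] * 10})
        m = pd.Series(False, index=t.index)
        with pytest.raises(DataError, match="bad_sample"):
            normalize_coverage(t, m)


def test_mismatch_nesting_on_simulated_reads(tmp_path):
    """Kept-read sets nest, so depth must be monotone in the threshold."""
    rng = np.random.default_rng(9)
    refs = {"s1": 60_000}
    recs = random_records(rng, refs, 800)
    bam = write_bam(tmp_path / "nest.bam", refs, recs)
    index = GenomeIndex(list(refs.items()))
    grid = make_window_grid(index, 5000)
    depth, _ = bam_window_coverage(bam, index, grid, 5000, [STRICT, INTER, UNB])
    assert (depth["0mm"] <= depth["2mm"] + 1e-12).all()
    assert (depth["2mm"] <= depth["unfiltered"] + 1e-12).all()
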