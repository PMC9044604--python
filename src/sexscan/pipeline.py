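"""Run orchestration: coverage -> heterozygosity -> sex statistics ->
(liftover) -> reporting, with content-digest stage caching.

The expensive stages (BAM traversal, VCF filtering) are cached under
``<output_dir>/cache`` keyed by content digests of their inputs, so
re-running with only plotting options changed (chromosome subset,
highlight list) touches no analysis tables.  Output tables are
tab-separated with 1-based inclusive coordinates (see the README written
next to them); all internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import coverage as cov
from . import heterozygosity as het
from . import sexdiff as sd
from . import synteny as syn
from .core import (
    GenomeIndex,
    RunConfig,
    Sample,
    assembly_n50,
    make_window_grid,
    validate_sample_sheet,
)
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


def ordered_metrics(config: RunConfig) -> list[str]:
    """Heterozygosity first, then coverage from strictest to unfiltered."""
    settings = sorted(
        config.mismatch_settings,
        key=lambda s: (s.max_mismatches is None, s.max_mismatches or 0),
    )
    return [sd.HET_METRIC] + [sd.coverage_metric(s.label) for s in settings]


def metric_fname(metric: str) -> str:
    return metric.replace("@", "_").replace("/", "_")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def obj_digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def write_table(df: pd.DataFrame, path: Path, coord_cols: bool = True) -> None:
    """Write a TSV, converting internal 0-based starts to 1-based inclusive."""
    out = df.copy()
    if coord_cols and "start" in out.columns:
        out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_table(path: Path, coord_cols: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if coord_cols and "start" in df.columns:
        df["start"] = df["start"] - 1
    return df


@dataclass
class BranchResult:
    """All per-branch (study- or synteny-coordinate) scan products."""

    name: str
    index: GenomeIndex
    unit_grid: pd.DataFrame
    masked: pd.Series
    unit_values: dict[str, pd.DataFrame]
    unit_roles: dict[str, pd.DataFrame]
    agg: dict[int, dict[str, pd.DataFrame]] = field(default_factory=dict)
    bands: dict[int, dict[str, Optional[sd.ConfidenceBand]]] = field(default_factory=dict)
    profiles: dict[int, dict[str, pd.DataFrame]] = field(default_factory=dict)
    scaffold_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    chrom_summary: dict[int, pd.DataFrame] = field(default_factory=dict)
    medians: dict[int, pd.Series] = field(default_factory=dict)


@dataclass
class RunResult:
    config: RunConfig
    index: GenomeIndex
    samples: list[Sample]
    branches: dict[str, BranchResult]
    sample_stats: pd.DataFrame
    anchoring: Optional[dict] = None
    warnings: list[str] = field(default_factory=list)
    tables_dir: Optional[Path] = None
    plots: dict[str, Path] = field(default_factory=dict)
    report_path: Optional[Path] = None


# ------------------------------------------------------------------ stages


def _coverage_stage(config, index, grid, samples, cache_dir, manifest):
    digest = obj_digest(
        {
            "bams": {s.id: file_digest(s.alignment_path) for s in samples},
            "unit_window": config.unit_window,
            "settings": [(s.label, s.max_mismatches) for s in config.mismatch_settings],
            "min_mapq": config.min_mapq,
        }
    )
    labels = [s.label for s in config.mismatch_settings]
    paths = {l: cache_dir / f"coverage_raw_{metric_fname(l)}.tsv" for l in labels}
    stats_path = cache_dir / "coverage_stats.json"
    if manifest.get("coverage") == digest and all(p.exists() for p in paths.values()) and stats_path.exists():
        log.info("coverage: cache hit, skipping BAM traversal")
        raw = {l: pd.read_csv(p, sep="\t").set_index("window_id") for l, p in paths.items()}
        stats = json.loads(stats_path.read_text())
        return raw, stats, digest
    raw = {l: pd.DataFrame(index=grid.index) for l in labels}
    stats = {}
    for s in samples:
        log.info("coverage: scanning %s", s.alignment_path)
        depth, fstats = cov.bam_window_coverage(
            s.alignment_path, index, grid, config.unit_window,
            config.mismatch_settings, min_mapq=config.min_mapq,
        )
        for l in labels:
            raw[l][s.id] = depth[l]
        stats[s.id] = {
            "total_records": fstats.total,
            "kept": fstats.kept,
            "aligned_bases": fstats.aligned_bases,
            "missing_nm_fraction": fstats.missing_nm_fraction,
        }
    for l, p in paths.items():
        raw[l].rename_axis("window_id").reset_index().to_csv(p, sep="\t", index=False)
    stats_path.write_text(json.dumps(stats, indent=1))
    return raw, stats, digest


def _het_stage(config, index, grid, samples, cache_dir, manifest):
    digest = obj_digest(
        {
            "vcf": file_digest(config.vcf),
            "unit_window": config.unit_window,
            "qual": [config.min_site_qual, config.min_genotype_qual, config.min_depth],
            "samples": sorted(s.id for s in samples),
        }
    )
    table_path = cache_dir / "het_unit.tsv"
    meta_path = cache_dir / "het_meta.json"
    if manifest.get("heterozygosity") == digest and table_path.exists() and meta_path.exists():
        log.info("heterozygosity: cache hit, skipping VCF traversal")
        table = pd.read_csv(table_path, sep="\t").set_index("window_id")
        meta = json.loads(meta_path.read_text())
        return table, meta, digest
    ids = [s.id for s in samples]
    variants = het.filter_variants(
        config.vcf, ids, config.min_site_qual, config.min_genotype_qual, config.min_depth
    )
    table = het.window_heterozygosity(variants, grid, index, config.unit_window)
    gw = het.genomewide_heterozygosity(variants, index)
    meta = {"genomewide_het_pct": gw.to_dict(), "dropped": variants.dropped,
            "kept_sites": int(len(variants.sites))}
    table.rename_axis("window_id").reset_index().to_csv(table_path, sep="\t", index=False)
    meta_path.write_text(json.dumps(meta, indent=1))
    return table, meta, digest


def _branch_stats(
    name: str,
    index: GenomeIndex,
    unit_grid: pd.DataFrame,
    masked: pd.Series,
    unit_values: dict[str, pd.DataFrame],
    samples: list[Sample],
    config: RunConfig,
    warnings: list[str],
) -> BranchResult:
    """Sex-group means, aggregation, bands, outliers and summaries."""
    metrics = ordered_metrics(config)
    unit_roles = {
        m: sd.sex_group_means(unit_values[m], samples) for m in metrics
    }
    br = BranchResult(name, index, unit_grid, masked, unit_values, unit_roles)
    unit_diffs = {m: unit_roles[m]["diff"] for m in metrics}
    br.scaffold_summary = sd.per_scaffold_summary(unit_diffs, unit_grid, index, masked)
    for rw in config.report_windows:
        agg, bands = {}, {}
        for m in metrics:
            a = sd.aggregate_windows(
                unit_roles[m], unit_grid, index, rw, config.unit_window,
                masked=masked, min_contributing=config.min_contributing,
            )
            band = sd.confidence_band(
                a.loc[~a["short"], "diff"], m, method=config.band_method
            )
            if band is None:
                warnings.append(
                    f"{name}: too few report windows at {rw} bp for a 95% band on {m}"
                )
            a["outlier"] = sd.flag_outlier_windows(a["diff"], band)
            agg[m], bands[m] = a, band
        br.agg[rw] = agg
        br.bands[rw] = bands
        br.profiles[rw] = sd.per_sample_profiles(
            unit_values, unit_grid, index, rw, config.unit_window,
            masked=masked, min_contributing=config.min_contributing,
        )
        br.chrom_summary[rw], br.medians[rw] = sd.per_chromosome_summary(agg)
    return br


def _synteny_branch(config, study: BranchResult, samples, warnings):
    smap = syn.parse_alignment_map(config.synteny_map, config.synteny_dialect)
    anchors, rate = syn.liftover_table(
        study.unit_grid, smap, min_overlap=config.anchor_min_overlap
    )
    anchoring = {
        "total_unit_windows": int(len(study.unit_grid)),
        "anchored_unit_windows": int(anchors["anchored"].sum()),
        "rate_pct": 100.0 * rate,
    }
    if not anchors["anchored"].any():
        warnings.append("synteny: no unit window could be anchored; branch skipped")
        return None, anchoring
    lgrid = syn.lifted_unit_grid(study.unit_grid, anchors, config.unit_window)
    lvalues = {m: v.loc[lgrid.index] for m, v in study.unit_values.items()}
    lmasked = study.masked.loc[lgrid.index]
    tindex = smap.target_index()
    br = _branch_stats(
        "synteny", tindex, lgrid, lmasked, lvalues, samples, config, warnings
    )
    return br, anchoring


# ------------------------------------------------------------------ tables

TABLE_README = """\
sexscan output tables
=====================
All coordinates are printed 1-based inclusive (internal arithmetic is
0-based half-open).  Files are tab-separated.  Columns:

*_unit_<metric>.tsv          per unit-window values
  scaffold/start/end         window coordinates
  masked                     extreme-coverage window, excluded downstream
  short                      trailing window shorter than half the unit size
  <sample ids>               normalized coverage (genome mean 1) or
                             heterozygous sites per bp for the sample
  heterogametic/homogametic  unweighted role means
  diff                       heterogametic - homogametic

*_window<N>_<metric>.tsv     report-window (N bp) aggregation
  n                          contributing unit windows (<min set missing)
  outlier                    none/high/low vs the genome-wide 95% band

*_outliers_window<N>_<metric>.tsv   the high/low rows of the above
*_profiles_window<N>_<metric>.tsv   per-sample aggregated tracks
*_scaffold_summary.tsv       per-scaffold mean differences and length
*_chromosome_summary_window<N>.tsv  mean/SD/n of differences per scaffold
*_medians_window<N>.tsv      genome-wide median difference per metric
bands.tsv                    95% band per branch/report window/metric
sample_stats.tsv             per-sample mean depth and heterozygosity %
assembly_stats.tsv           scaffold count, total length, N50
anchoring.tsv                liftover anchoring statistics (synteny runs)

Metrics: heterozygosity, coverage_<mismatch setting label>.
The difference sign convention is heterogametic minus homogametic in both
XY and ZW systems: differentiated sex-linked regions give negative
coverage differences, low-differentiation regions positive
heterozygosity differences.
"""


def _write_branch_tables(br: BranchResult, tables_dir: Path, config: RunConfig) -> list[Path]:
    paths = []

    def _save(df, fname, coord=True):
        p = tables_dir / fname
        write_table(df, p, coord_cols=coord)
        paths.append(p)
        return p

    metrics = ordered_metrics(config)
    for m in metrics:
        unit = pd.concat(
            [
                br.unit_grid[["scaffold", "start", "end"]],
                pd.DataFrame({"masked": br.masked.to_numpy(), "short": br.unit_grid["short"].to_numpy()},
                             index=br.unit_grid.index),
                br.unit_values[m],
                br.unit_roles[m],
            ],
            axis=1,
        )
        _save(unit, f"{br.name}_unit_{metric_fname(m)}.tsv")
    for rw, agg in br.agg.items():
        for m in metrics:
            a = agg[m][["scaffold", "start", "end", "n",
                        "heterogametic", "homogametic", "diff", "outlier"]]
            _save(a, f"{br.name}_window{rw}_{metric_fname(m)}.tsv")
            _save(
                a[a["outlier"] != "none"],
                f"{br.name}_outliers_window{rw}_{metric_fname(m)}.tsv",
            )
        for m in metrics:
            prof = br.profiles[rw][m].drop(columns=["length", "short"])
            _save(prof, f"{br.name}_profiles_window{rw}_{metric_fname(m)}.tsv")
        _save(br.chrom_summary[rw], f"{br.name}_chromosome_summary_window{rw}.tsv", coord=False)
        med = br.medians[rw].rename_axis("metric").rename("median").reset_index()
        _save(med, f"{br.name}_medians_window{rw}.tsv", coord=False)
    _save(br.scaffold_summary.reset_index(), f"{br.name}_scaffold_summary.tsv", coord=False)
    return paths


def _write_shared_tables(result: RunResult, tables_dir: Path) -> None:
    rows = []
    for bname, br in result.branches.items():
        if br is None:
            continue
        for rw, bands in br.bands.items():
            for m, b in bands.items():
                if b is not None:
                    rows.append((bname, rw, m, b.low, b.high, b.method))
    pd.DataFrame(
        rows, columns=["branch", "report_window", "metric", "low", "high", "method"]
    ).to_csv(tables_dir / "bands.tsv", sep="\t", index=False)
    result.sample_stats.to_csv(tables_dir / "sample_stats.tsv", sep="\t", index=False)
    arows = []
    for bname, br in result.branches.items():
        if br is None:
            continue
        idx = br.index
        arows.append((bname, len(idx), idx.total_length, assembly_n50(idx)))
    pd.DataFrame(
        arows, columns=["branch", "scaffolds", "total_length", "n50"]
    ).to_csv(tables_dir / "assembly_stats.tsv", sep="\t", index=False)
    if result.anchoring is not None:
        pd.DataFrame([result.anchoring]).to_csv(
            tables_dir / "anchoring.tsv", sep="\t", index=False
        )
    (tables_dir / "README.txt").write_text(TABLE_README)


# --------------------------------------------------------------------- run


def run_pipeline(config: RunConfig, render: bool = True) -> RunResult:
    """Execute the full scan as configured and write all outputs."""
    config.validate()
    if config.reference is None:
        raise ConfigError("a reference FASTA (or its .fai) is required")
    if config.vcf is None:
        raise ConfigError("a multi-sample VCF is required")
    samples = validate_sample_sheet(config.samples, config)
    index = GenomeIndex.from_fasta(config.reference)
    grid = make_window_grid(index, config.unit_window)

    outdir = Path(config.output_dir)
    cache_dir = outdir / "cache"
    tables_dir = outdir / "tables"
    for d in (outdir, cache_dir, tables_dir):
        d.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    warnings: list[str] = []

    raw, cov_stats, cov_digest = _coverage_stage(
        config, index, grid, samples, cache_dir, manifest
    )
    het_table, het_meta, het_digest = _het_stage(
        config, index, grid, samples, cache_dir, manifest
    )

    unb = config.unbounded_setting.label
    masked = cov.mask_outlier_windows(raw[unb], config.mask_factor)
    unit_values: dict[str, pd.DataFrame] = {sd.HET_METRIC: het_table}
    for s in config.mismatch_settings:
        unit_values[sd.coverage_metric(s.label)] = cov.normalize_coverage(
            raw[s.label], masked
        )

    for sid, frac in ((k, v["missing_nm_fraction"]) for k, v in cov_stats.items()):
        if frac > 0.01:
            warnings.append(f"sample {sid}: {100*frac:.1f}% of reads lack NM tags")
    for sid, pct in het_meta["genomewide_het_pct"].items():
        if pct >= 1.0:
            warnings.append(
                f"sample {sid}: genome-wide heterozygosity {pct:.2f}% >= 1%; "
                "the sex-linked signal may be unreliable at this diversity"
            )

    study = _branch_stats(
        "study", index, grid, masked, unit_values, samples, config, warnings
    )
    branches = {"study": study}
    anchoring = None
    if config.synteny_map:
        sbr, anchoring = _synteny_branch(config, study, samples, warnings)
        if sbr is not None:
            branches["synteny"] = sbr

    stats_rows = []
    for s in samples:
        cs = cov_stats[s.id]
        stats_rows.append(
            {
                "sample": s.id,
                "sex": s.sex_label,
                "role": s.role,
                "mean_depth_unfiltered": cs["aligned_bases"][unb] / index.total_length,
                "total_records": cs["total_records"],
                "kept_unfiltered": cs["kept"][unb],
                "missing_nm_fraction": cs["missing_nm_fraction"],
                "genomewide_het_pct": het_meta["genomewide_het_pct"][s.id],
            }
        )
    result = RunResult(
        config=config,
        index=index,
        samples=samples,
        branches=branches,
        sample_stats=pd.DataFrame(stats_rows),
        anchoring=anchoring,
        warnings=warnings,
        tables_dir=tables_dir,
    )

    for br in branches.values():
        _write_branch_tables(br, tables_dir, config)
    _write_shared_tables(result, tables_dir)

    manifest.update({"coverage": cov_digest, "heterozygosity": het_digest})
    if render:
        from . import reporting

        result.plots, result.report_path = reporting.render_all(result)
        manifest["reporting"] = obj_digest(
            {"chromosomes": config.chromosomes, "highlight": config.highlight}
        )
    manifest_path.write_text(json.dumps(manifest, indent=1))
    for w in warnings:
        log.warning("%s", w)
    return result


def render_only(config: RunConfig) -> dict:
    """Rebuild plots and the HTML report from cached tables only."""
    outdir = Path(config.output_dir)
    manifest_path = outdir / MANIFEST_NAME
    tables_dir = outdir / "tables"
    if not manifest_path.exists() or not tables_dir.exists():
        raise DataError(
            f"no prior run found under {outdir}; run `sexscan run` before `sexscan render`"
        )
    from . import reporting

    return reporting.render_from_tables(config, outdir)
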