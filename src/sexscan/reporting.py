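"""Rendering: the five plot types, outlier tables and the HTML report.

All plots are multi-page PDFs whose last page lists the paths of the
tables they were drawn from, so every figure is traceable to its data.
Rendering consumes only the written tables (or their in-memory
equivalents), which keeps re-plotting with a different chromosome subset
or highlight list independent of the analysis stages.

Colour semantics are fixed: red = above the 95% band, blue = below,
grey = the band itself; highlighted scaffolds use a qualitative palette,
everything else is grey.
"""

from __future__ import annotations

import base64
import glob
import html as html_mod
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .core import RunConfig
from .errors import ConfigError, DataError
from .pipeline import metric_fname, ordered_metrics, read_table
from .sexdiff import HET_METRIC

log = logging.getLogger(__name__)

HIGH_COLOR, LOW_COLOR, NEUTRAL_COLOR, BAND_COLOR = "#c0392b", "#2462ab", "#444444", "#d5d5d5"
PALETTE = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628"]


@dataclass
class BranchView:
    """The slice of run output one branch's plots are drawn from."""

    name: str
    scaffold_order: list[str]
    scaffold_lengths: dict[str, int]
    agg: dict[int, dict[str, pd.DataFrame]]
    bands: dict[int, dict[str, Optional[tuple[float, float]]]]
    profiles: dict[int, dict[str, pd.DataFrame]]
    scaffold_summary: pd.DataFrame
    chrom_summary: dict[int, pd.DataFrame]
    medians: dict[int, pd.Series]
    table_paths: list[str] = field(default_factory=list)


def _metric_label(metric: str) -> str:
    if metric == HET_METRIC:
        return "heterozygosity (sites/bp)"
    return f"coverage ({metric.split('@', 1)[1]})"


def branch_view_from_result(result, branch_name: str) -> BranchView:
    br = result.branches[branch_name]
    bands = {
        rw: {m: (None if b is None else (b.low, b.high)) for m, b in d.items()}
        for rw, d in br.bands.items()
    }
    tdir = result.tables_dir
    paths = sorted(str(p) for p in tdir.glob(f"{branch_name}_*.tsv")) if tdir else []
    return BranchView(
        name=branch_name,
        scaffold_order=br.index.names,
        scaffold_lengths=dict(br.index.lengths),
        agg=br.agg,
        bands=bands,
        profiles=br.profiles,
        scaffold_summary=br.scaffold_summary.reset_index(),
        chrom_summary=br.chrom_summary,
        medians=br.medians,
        table_paths=paths,
    )


def branch_view_from_tables(tables_dir: Path, branch_name: str, config: RunConfig) -> BranchView:
    metrics = ordered_metrics(config)
    agg: dict[int, dict[str, pd.DataFrame]] = {}
    profiles: dict[int, dict[str, pd.DataFrame]] = {}
    pat = re.compile(rf"{re.escape(branch_name)}_window(\d+)_(.+)\.tsv$")
    fname_to_metric = {metric_fname(m): m for m in metrics}
    for p in sorted(tables_dir.glob(f"{branch_name}_window*_*.tsv")):
        m = pat.match(p.name)
        if not m:
            continue
        rw, mf = int(m.group(1)), m.group(2)
        if mf not in fname_to_metric:
            continue
        agg.setdefault(rw, {})[fname_to_metric[mf]] = read_table(p)
    for p in sorted(tables_dir.glob(f"{branch_name}_profiles_window*_*.tsv")):
        m = re.match(rf"{re.escape(branch_name)}_profiles_window(\d+)_(.+)\.tsv$", p.name)
        if not m or m.group(2) not in fname_to_metric:
            continue
        profiles.setdefault(int(m.group(1)), {})[fname_to_metric[m.group(2)]] = read_table(p)
    if not agg:
        raise DataError(f"no cached {branch_name} tables under {tables_dir}")
    bands_df = pd.read_csv(tables_dir / "bands.tsv", sep="\t")
    bands: dict[int, dict[str, Optional[tuple[float, float]]]] = {}
    for rw in agg:
        bands[rw] = {}
        for metric in metrics:
            sel = bands_df[
                (bands_df["branch"] == branch_name)
                & (bands_df["report_window"] == rw)
                & (bands_df["metric"] == metric)
            ]
            bands[rw][metric] = (
                (float(sel["low"].iloc[0]), float(sel["high"].iloc[0])) if len(sel) else None
            )
    summary = read_table(tables_dir / f"{branch_name}_scaffold_summary.tsv", coord_cols=False)
    chrom_summary, medians = {}, {}
    for rw in agg:
        cs = tables_dir / f"{branch_name}_chromosome_summary_window{rw}.tsv"
        chrom_summary[rw] = pd.read_csv(cs, sep="\t")
        med = pd.read_csv(tables_dir / f"{branch_name}_medians_window{rw}.tsv", sep="\t")
        medians[rw] = med.set_index("metric")["median"]
    any_rw = next(iter(agg))
    any_m = next(iter(agg[any_rw]))
    order = list(dict.fromkeys(agg[any_rw][any_m]["scaffold"]))
    lengths = agg[any_rw][any_m].groupby("scaffold")["end"].max().to_dict()
    paths = sorted(str(p) for p in tables_dir.glob(f"{branch_name}_*.tsv"))
    return BranchView(
        branch_name, order, lengths, agg, bands, profiles,
        summary, chrom_summary, medians, paths,
    )


def _subset_order(view: BranchView, chromosomes: list[str]) -> list[str]:
    if not chromosomes:
        return view.scaffold_order
    order = [s for s in view.scaffold_order if s in set(chromosomes)]
    if not order:
        raise ConfigError(
            f"chromosome subset {chromosomes} matches nothing in the "
            f"{view.name} assembly (known: {view.scaffold_order[:10]}...)"
        )
    return order


def _genome_axis(view: BranchView, order: list[str]) -> tuple[dict[str, float], float]:
    offsets, acc = {}, 0.0
    for name in order:
        offsets[name] = acc
        acc += view.scaffold_lengths.get(name, 0)
    return offsets, acc


def _paths_page(pdf: PdfPages, paths: list[str], title: str) -> None:
    fig = plt.figure(figsize=(8.3, 11.7))
    fig.text(0.05, 0.96, f"{title}: source data tables", fontsize=11, weight="bold")
    body = "\n".join(paths) if paths else "(tables not written)"
    fig.text(0.05, 0.93, body, fontsize=6, va="top", family="monospace")
    pdf.savefig(fig)
    plt.close(fig)


def _save_png(fig, png_path: Optional[Path]) -> None:
    if png_path is not None:
        fig.savefig(png_path, dpi=90)


def render_genome_scan(
    view: BranchView, rw: int, metrics: list[str], out_pdf: Path,
    chromosomes: list[str] | None = None, png_path: Optional[Path] = None,
) -> Path:
    """Plot type 1: sex differences along the genome with the 95% band."""
    order = _subset_order(view, chromosomes or [])
    offsets, total = _genome_axis(view, order)
    with PdfPages(out_pdf) as pdf:
        fig, axes = plt.subplots(
            len(metrics), 1, figsize=(11, 2.1 * len(metrics)), sharex=True
        )
        axes = np.atleast_1d(axes)
        for ax, metric in zip(axes, metrics):
            a = view.agg[rw][metric]
            a = a[a["scaffold"].isin(order)]
            x = a["scaffold"].map(offsets).to_numpy() + (
                (a["start"] + a["end"]) / 2
            ).to_numpy()
            band = view.bands[rw].get(metric)
            if band is not None:
                ax.axhspan(band[0], band[1], color=BAND_COLOR, zorder=0)
            colors = np.where(
                a["outlier"] == "high", HIGH_COLOR,
                np.where(a["outlier"] == "low", LOW_COLOR, NEUTRAL_COLOR),
            )
            ax.scatter(x, a["diff"], s=6, c=colors, linewidths=0)
            for name in order[1:]:
                ax.axvline(offsets[name], color="#bbbbbb", lw=0.5)
            ax.set_ylabel(_metric_label(metric), fontsize=7)
        axes[-1].set_xlabel(f"genome position ({view.name} coordinates)")
        fig.suptitle(
            f"Sex differences (heterogametic - homogametic), {rw/1e6:g} Mb windows",
            fontsize=10,
        )
        fig.tight_layout()
        _save_png(fig, png_path)
        pdf.savefig(fig)
        plt.close(fig)
        _paths_page(pdf, view.table_paths, "Genome scan")
    return out_pdf


def render_per_sex_scan(
    view: BranchView, rw: int, metrics: list[str], out_pdf: Path,
    role_labels: dict[str, str], chromosomes: list[str] | None = None,
    png_path: Optional[Path] = None,
) -> Path:
    """Plot type 2: the same scan with each sex/role plotted separately."""
    order = _subset_order(view, chromosomes or [])
    offsets, _ = _genome_axis(view, order)
    with PdfPages(out_pdf) as pdf:
        fig, axes = plt.subplots(
            len(metrics), 1, figsize=(11, 2.1 * len(metrics)), sharex=True
        )
        axes = np.atleast_1d(axes)
        for ax, metric in zip(axes, metrics):
            a = view.agg[rw][metric]
            a = a[a["scaffold"].isin(order)]
            x = a["scaffold"].map(offsets).to_numpy() + (
                (a["start"] + a["end"]) / 2
            ).to_numpy()
            for role, color in (("heterogametic", "#b2533e"), ("homogametic", "#3e6fb2")):
                ax.scatter(
                    x, a[role], s=5, c=color, linewidths=0,
                    label=role_labels.get(role, role),
                )
            ax.set_ylabel(_metric_label(metric), fontsize=7)
        axes[0].legend(fontsize=6, loc="upper right")
        axes[-1].set_xlabel(f"genome position ({view.name} coordinates)")
        fig.suptitle(f"Per-role values, {rw/1e6:g} Mb windows", fontsize=10)
        fig.tight_layout()
        _save_png(fig, png_path)
        pdf.savefig(fig)
        plt.close(fig)
        _paths_page(pdf, view.table_paths, "Per-sex scan")
    return out_pdf


def _scaffold_colors(names: pd.Series, highlight: list[str]) -> list[str]:
    lut = {h: PALETTE[i % len(PALETTE)] for i, h in enumerate(highlight)}
    return [lut.get(n, "#999999") for n in names]


def render_scaffold_scatter(
    view: BranchView, cov_metrics: list[str], out_pdf: Path,
    highlight: list[str] | None = None, png_path: Optional[Path] = None,
) -> Path:
    """Plot type 3: per-scaffold differences, by mismatch stringency."""
    s = view.scaffold_summary
    highlight = highlight or []
    with PdfPages(out_pdf) as pdf:
        ncol = len(cov_metrics)
        fig, axes = plt.subplots(2, ncol, figsize=(3.4 * ncol, 6.4), squeeze=False)
        size = 8 + 40 * (s["length"] / max(s["length"].max(), 1))
        colors = _scaffold_colors(s["scaffold"], highlight)
        for j, metric in enumerate(cov_metrics):
            ax = axes[0][j]
            ax.scatter(s[metric], s[HET_METRIC], s=size, c=colors, alpha=0.7, linewidths=0)
            ax.set_xlabel(_metric_label(metric), fontsize=7)
            ax.set_ylabel("heterozygosity diff", fontsize=7)
            ax = axes[1][j]
            ax.scatter(s[metric], s["length"], s=10, c=colors, alpha=0.7, linewidths=0)
            ax.set_yscale("log")
            ax.set_xlabel(_metric_label(metric), fontsize=7)
            ax.set_ylabel("scaffold length (bp)", fontsize=7)
        fig.suptitle("Per-scaffold sex differences (point size ~ length)", fontsize=10)
        fig.tight_layout()
        _save_png(fig, png_path)
        pdf.savefig(fig)
        plt.close(fig)
        _paths_page(pdf, view.table_paths, "Scaffold scatter")
    return out_pdf


def render_chromosome_scatter(
    view: BranchView, rw: int, metrics: list[str], out_pdf: Path,
    highlight: list[str] | None = None, png_path: Optional[Path] = None,
) -> Path:
    """Plot type 4: mean ± SD per chromosome with genome-wide median lines."""
    highlight = highlight or []
    known = set(view.scaffold_order)
    bad = [h for h in highlight if h not in known]
    if bad:
        raise ConfigError(
            f"highlight names {bad} not in the {view.name} assembly; "
            f"valid names: {sorted(known)}"
        )
    cs = view.chrom_summary[rw]
    cov_metrics = [m for m in metrics if m != HET_METRIC]
    rows = [HET_METRIC] * len(cov_metrics) + cov_metrics  # 2 x n_settings panels
    with PdfPages(out_pdf) as pdf:
        ncol = len(cov_metrics)
        fig, axes = plt.subplots(2, ncol, figsize=(3.6 * ncol, 7.2), squeeze=False)
        order = view.scaffold_order
        xpos = {n: i for i, n in enumerate(order)}
        for row in (0, 1):
            for j in range(ncol):
                metric = HET_METRIC if row == 0 else cov_metrics[j]
                ax = axes[row][j]
                d = cs[cs["metric"] == metric]
                d = d[d["scaffold"].isin(xpos)]
                x = d["scaffold"].map(xpos)
                sizes = 8 + 40 * d["scaffold"].map(view.scaffold_lengths).fillna(0) / max(
                    view.scaffold_lengths.values()
                )
                colors = _scaffold_colors(d["scaffold"], highlight)
                ax.errorbar(
                    x, d["mean"], yerr=d["sd"], fmt="none",
                    ecolor="#bbbbbb", elinewidth=0.8, zorder=1,
                )
                ax.scatter(x, d["mean"], s=sizes, c=colors, zorder=2, linewidths=0)
                med = view.medians[rw].get(metric, np.nan)
                if np.isfinite(med):
                    ax.axhline(med, ls="--", color="#555555", lw=0.8)
                ax.set_xticks(range(len(order)))
                ax.set_xticklabels(order, rotation=90, fontsize=5)
                ax.set_title(_metric_label(metric), fontsize=8)
        fig.suptitle(
            f"Per-chromosome mean ± SD of sex differences ({rw/1e6:g} Mb windows); "
            "dashed line = genome-wide median", fontsize=9,
        )
        fig.tight_layout()
        _save_png(fig, png_path)
        pdf.savefig(fig)
        plt.close(fig)
        _paths_page(pdf, view.table_paths, "Chromosome scatter")
    return out_pdf


def render_sample_profiles(
    view: BranchView, rw: int, metrics: list[str], out_pdf: Path,
    sample_stats: pd.DataFrame, chromosomes: list[str] | None = None,
    png_path: Optional[Path] = None,
) -> Path:
    """Plot type 5: one page per sample x mismatch setting.

    Each page shows the sample's normalized coverage and heterozygosity
    tracks; the caption carries the sample's genome-wide mean depth so
    mis-sexed or under-sequenced samples stand out.
    """
    order = _subset_order(view, chromosomes or [])
    offsets, _ = _genome_axis(view, order)
    cov_metrics = [m for m in metrics if m != HET_METRIC]
    het_prof = view.profiles[rw][HET_METRIC]
    samples = list(sample_stats["sample"])
    depth = dict(zip(sample_stats["sample"], sample_stats["mean_depth_unfiltered"]))
    sexes = dict(zip(sample_stats["sample"], sample_stats["sex"]))
    first = True
    with PdfPages(out_pdf) as pdf:
        for sid in samples:
            for metric in cov_metrics:
                prof = view.profiles[rw][metric]
                sel = prof["scaffold"].isin(order)
                x = prof.loc[sel, "scaffold"].map(offsets).to_numpy() + (
                    (prof.loc[sel, "start"] + prof.loc[sel, "end"]) / 2
                ).to_numpy()
                fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(11, 4.2), sharex=True)
                ax1.scatter(x, prof.loc[sel, str(sid)], s=5, c="#3e6fb2", linewidths=0)
                ax1.set_ylabel("normalized coverage", fontsize=7)
                ax2.scatter(x, het_prof.loc[sel, str(sid)], s=5, c="#b2533e", linewidths=0)
                ax2.set_ylabel("heterozygosity (sites/bp)", fontsize=7)
                ax2.set_xlabel(f"genome position ({view.name} coordinates)")
                fig.suptitle(
                    f"sample {sid} ({sexes[sid]}) — {_metric_label(metric)} — "
                    f"mean unfiltered depth {depth[sid]:.2f}x",
                    fontsize=9,
                )
                fig.tight_layout()
                if first:
                    _save_png(fig, png_path)
                    first = False
                pdf.savefig(fig)
                plt.close(fig)
        _paths_page(pdf, view.table_paths, "Sample profiles")
    return out_pdf


# ------------------------------------------------------------------- HTML

_HTML_SHELL = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>sexscan report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
table {{ border-collapse: collapse; font-size: 0.85em; }}
td, th {{ border: 1px solid #ccc; padding: 2px 8px; }}
h2 {{ border-bottom: 1px solid #999; }}
.warn {{ color: #a33; }}
img {{ max-width: 100%; }}
.placeholder {{ color: #777; font-style: italic; }}
</style></head><body>
<h1>sexscan run report</h1>
{body}
</body></html>
"""

PLOT_DESCRIPTIONS = {
    1: "Genome scan of sex differences (heterogametic - homogametic) per "
       "report window; grey band = genome-wide 95% interval, red/blue = "
       "windows above/below it. Sex-linked regions appear as runs of "
       "outliers: negative coverage differences indicate Y/W degeneration, "
       "positive heterozygosity differences indicate low differentiation.",
    2: "The same scan plotted for each role separately; use it to check "
       "that a signal is driven by the heterogametic sex rather than by "
       "deviations in the homogametic sex.",
    3: "Per-scaffold differences by mismatch stringency; autosomal, "
       "high- and low-differentiation scaffolds form separate clusters, "
       "and the low-differentiation cluster converges towards the "
       "autosomal one as mismatches are allowed.",
    4: "Per-chromosome mean ± SD of window differences; dashed lines mark "
       "the genome-wide medians; highlighted chromosomes are coloured.",
    5: "Per-sample coverage and heterozygosity profiles; a mis-sexed "
       "sample tracks the opposite role over sex-linked regions.",
}


def _df_html(df: pd.DataFrame, max_rows: int = 200) -> str:
    if df is None or df.empty:
        return '<p class="placeholder">no rows</p>'
    return df.head(max_rows).to_html(index=False, border=0)


def _embed_png(png: Optional[Path]) -> str:
    if png is None or not Path(png).exists():
        return '<p class="placeholder">plot not available</p>'
    data = base64.b64encode(Path(png).read_bytes()).decode()
    return f'<img src="data:image/png;base64,{data}"/>'


def build_html_report(
    out_path: Path,
    tables_dir: Path,
    plot_pngs: dict[str, Path],
    plot_pdfs: dict[str, Path],
    sample_stats: Optional[pd.DataFrame],
    assembly_stats: Optional[pd.DataFrame],
    anchoring: Optional[pd.DataFrame],
    warnings: list[str],
) -> Path:
    """Assemble the static single-file HTML report."""
    parts: list[str] = []
    if warnings:
        parts.append("<h2>Warnings</h2><ul>" + "".join(
            f'<li class="warn">{html_mod.escape(w)}</li>' for w in warnings
        ) + "</ul>")
    parts.append("<h2>Assembly statistics</h2>")
    parts.append(_df_html(assembly_stats) if assembly_stats is not None
                 else '<p class="placeholder">assembly statistics unavailable</p>')
    parts.append("<h2>Samples</h2>")
    parts.append(_df_html(sample_stats) if sample_stats is not None
                 else '<p class="placeholder">sample statistics unavailable</p>')
    if anchoring is not None and len(anchoring):
        rate = float(anchoring["rate_pct"].iloc[0])
        parts.append(
            "<h2>Synteny liftover</h2>"
            f"<p>Anchoring rate: <b>{rate:.1f}%</b> of unit windows were "
            "lifted onto the synteny assembly.</p>" + _df_html(anchoring)
        )
    for key in sorted(plot_pdfs):
        ptype = int(key.split("plot")[1][0])
        parts.append(f"<h2>{key}</h2><p>{PLOT_DESCRIPTIONS.get(ptype, '')}</p>")
        parts.append(f'<p>PDF: <a href="{plot_pdfs[key]}">{plot_pdfs[key]}</a></p>')
        parts.append(_embed_png(plot_pngs.get(key)))
    parts.append("<h2>Outlier tables</h2>")
    outlier_files = sorted(glob.glob(str(tables_dir / "*_outliers_*.tsv")))
    if not outlier_files:
        parts.append('<p class="placeholder">no outlier tables were written</p>')
    for f in outlier_files:
        df = pd.read_csv(f, sep="\t")
        parts.append(f"<h3>{Path(f).name}</h3>")
        parts.append(_df_html(df) if len(df) else '<p class="placeholder">no outlier windows</p>')
    out_path.write_text(_HTML_SHELL.format(body="\n".join(parts)))
    return out_path


# --------------------------------------------------------------- drivers


def _role_labels(sample_stats: pd.DataFrame) -> dict[str, str]:
    labels = {}
    for role in ("heterogametic", "homogametic"):
        sel = sample_stats[sample_stats["role"] == role]
        ids = ", ".join(f"{r['sample']} ({r.sex})" for _, r in sel.iterrows())
        labels[role] = f"{role}: {ids}" if ids else role
    return labels


def _render_branch(view, config, plots_dir, png_dir, sample_stats):
    metrics = ordered_metrics(config)
    cov_metrics = [m for m in metrics if m != HET_METRIC]
    rw = max(view.agg)  # largest configured report window drives the figures
    out: dict[str, Path] = {}
    pngs: dict[str, Path] = {}
    # chromosome/highlight names live in one branch's coordinate space;
    # restrict each list to the names this branch actually has
    known = set(view.scaffold_order)
    chrom_subset = [c for c in config.chromosomes if c in known]
    highlight = [h for h in config.highlight if h in known]
    matched = {
        "chromosomes": bool(chrom_subset) or not config.chromosomes,
        "highlight": bool(highlight) or not config.highlight,
    }
    config = type(config)(**{**config.__dict__, "chromosomes": chrom_subset,
                             "highlight": highlight})

    def _p(n, stem):
        pdf = plots_dir / f"{view.name}_plot{n}_{stem}.pdf"
        png = png_dir / f"{view.name}_plot{n}_{stem}.png"
        return pdf, png

    pdf, png = _p(1, "genome_scan")
    render_genome_scan(view, rw, metrics, pdf, config.chromosomes, png)
    out[f"{view.name}_plot1_genome_scan"], pngs[f"{view.name}_plot1_genome_scan"] = pdf, png
    pdf, png = _p(2, "per_sex_scan")
    render_per_sex_scan(view, rw, metrics, pdf, _role_labels(sample_stats),
                        config.chromosomes, png)
    out[f"{view.name}_plot2_per_sex_scan"], pngs[f"{view.name}_plot2_per_sex_scan"] = pdf, png
    pdf, png = _p(3, "scaffold_scatter")
    render_scaffold_scatter(view, cov_metrics, pdf, config.highlight, png)
    out[f"{view.name}_plot3_scaffold_scatter"], pngs[f"{view.name}_plot3_scaffold_scatter"] = pdf, png
    pdf, png = _p(4, "chromosome_scatter")
    render_chromosome_scatter(view, rw, metrics, pdf, config.highlight, png)
    out[f"{view.name}_plot4_chromosome_scatter"], pngs[f"{view.name}_plot4_chromosome_scatter"] = pdf, png
    pdf, png = _p(5, "sample_profiles")
    render_sample_profiles(view, rw, metrics, pdf, sample_stats, config.chromosomes, png)
    out[f"{view.name}_plot5_sample_profiles"], pngs[f"{view.name}_plot5_sample_profiles"] = pdf, png
    return out, pngs, matched


def _check_name_matches(config: RunConfig, matched_any: dict[str, bool],
                        branches: list[str]) -> None:
    if config.chromosomes and not matched_any["chromosomes"]:
        raise ConfigError(
            f"chromosome subset {config.chromosomes} matches nothing in any "
            f"rendered branch ({branches})"
        )
    if config.highlight and not matched_any["highlight"]:
        raise ConfigError(
            f"highlight names {config.highlight} match nothing in any "
            f"rendered branch ({branches})"
        )


def render_all(result) -> tuple[dict[str, Path], Path]:
    """Render every plot and the HTML report for a completed run."""
    outdir = Path(result.config.output_dir)
    plots_dir = outdir / "plots"
    png_dir = plots_dir / "png"
    plots_dir.mkdir(parents=True, exist_ok=True)
    png_dir.mkdir(parents=True, exist_ok=True)
    all_plots: dict[str, Path] = {}
    all_pngs: dict[str, Path] = {}
    matched_any: dict[str, bool] = {"chromosomes": False, "highlight": False}
    for bname in result.branches:
        view = branch_view_from_result(result, bname)
        plots, pngs, matched = _render_branch(view, result.config, plots_dir, png_dir,
                                              result.sample_stats)
        all_plots.update(plots)
        all_pngs.update(pngs)
        for k in matched_any:
            matched_any[k] |= matched[k]
    _check_name_matches(result.config, matched_any, list(result.branches))
    tdir = result.tables_dir
    assembly = pd.read_csv(tdir / "assembly_stats.tsv", sep="\t")
    anch_path = tdir / "anchoring.tsv"
    anchoring = pd.read_csv(anch_path, sep="\t") if anch_path.exists() else None
    report = build_html_report(
        outdir / "report.html", tdir, all_pngs, all_plots,
        result.sample_stats, assembly, anchoring, result.warnings,
    )
    return all_plots, report


def render_from_tables(config: RunConfig, outdir: Path) -> dict:
    """Re-render plots/report from the cached tables of a prior run."""
    tables_dir = outdir / "tables"
    plots_dir = outdir / "plots"
    png_dir = plots_dir / "png"
    plots_dir.mkdir(parents=True, exist_ok=True)
    png_dir.mkdir(parents=True, exist_ok=True)
    stats_path = tables_dir / "sample_stats.tsv"
    if not stats_path.exists():
        raise DataError(f"missing cached tables under {tables_dir}")
    sample_stats = pd.read_csv(stats_path, sep="\t")
    branches = sorted(
        {p.name.split("_window")[0] for p in tables_dir.glob("*_window*_*.tsv")
         if "_profiles_" not in p.name and "_outliers_" not in p.name}
    )
    all_plots: dict[str, Path] = {}
    all_pngs: dict[str, Path] = {}
    matched_any: dict[str, bool] = {"chromosomes": False, "highlight": False}
    for bname in branches:
        view = branch_view_from_tables(tables_dir, bname, config)
        plots, pngs, matched = _render_branch(view, config, plots_dir, png_dir, sample_stats)
        all_plots.update(plots)
        all_pngs.update(pngs)
        for k in matched_any:
            matched_any[k] |= matched[k]
    _check_name_matches(config, matched_any, branches)
    assembly_path = tables_dir / "assembly_stats.tsv"
    assembly = pd.read_csv(assembly_path, sep="\t") if assembly_path.exists() else None
    anch_path = tables_dir / "anchoring.tsv"
    anchoring = pd.read_csv(anch_path, sep="\t") if anch_path.exists() else None
    report = build_html_report(
        outdir / "report.html", tables_dir, all_pngs, all_plots,
        sample_stats, assembly, anchoring, [],
    )
    return {"plots": all_plots, "report": report}
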