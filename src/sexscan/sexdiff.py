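"""Sex-group means, differences, aggregation, 95% band and outlier flags.

The contrast is always heterogametic minus homogametic, for both XY and
ZW systems: differentiated sex-linked regions then show negative coverage
differences (Y/W degeneration removes reads from the heterogametic sex)
and low-differentiation regions show positive heterozygosity differences
(gametolog divergence appears as excess heterozygosity).

The "95% confidence interval" of the genome scan is implemented, by
default, as the empirical 2.5th/97.5th percentiles of the genome-wide
distribution of window differences — i.e. an outlier band, not a
standard-error interval (which would flag nearly every window in a
genome-sized sample).  A mean ± 1.96 SD variant is available via
``band_method="stddev"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomeIndex, HETEROGAMETIC, HOMOGAMETIC, Sample, make_window_grid
from .errors import ConfigError

log = logging.getLogger(__name__)

#: metric key for the heterozygosity scan (coverage metrics are
#: ``coverage@<setting label>``)
HET_METRIC = "heterozygosity"


def coverage_metric(setting_label: str) -> str:
    return f"coverage@{setting_label}"


@dataclass(frozen=True)
class ConfidenceBand:
    metric: str
    low: float
    high: float
    method: str

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("band low > high")


def sex_group_means(values: pd.DataFrame, samples: Sequence[Sample]) -> pd.DataFrame:
    """Unweighted per-role means of per-sample window values.

    Single-sample roles pass through unchanged.  Returns columns
    ``heterogametic, homogametic, diff`` (heterogametic − homogametic).
    """
    by_role = {HETEROGAMETIC: [], HOMOGAMETIC: []}
    for s in samples:
        if s.role is None:
            raise ConfigError(f"sample {s.id!r} has no assigned role; validate the sheet first")
        by_role[s.role].append(s.id)
    out = pd.DataFrame(index=values.index)
    for role, ids in by_role.items():
        out[role] = values[ids].mean(axis=1)
    out["diff"] = out[HETEROGAMETIC] - out[HOMOGAMETIC]
    return out


def sex_difference(means: pd.DataFrame) -> pd.Series:
    """Heterogametic − homogametic (antisymmetric under role swap)."""
    return means[HETEROGAMETIC] - means[HOMOGAMETIC]


def aggregate_windows(
    unit_values: pd.DataFrame,
    unit_grid: pd.DataFrame,
    index: GenomeIndex,
    report_window: int,
    unit_window: int,
    masked: Optional[pd.Series] = None,
    min_contributing: int = 5,
) -> pd.DataFrame:
    """Mean unit-window values per report window, binned by unit midpoint.

    Masked and short unit windows do not contribute.  Report windows with
    fewer than ``min_contributing`` contributing unit windows are set
    missing (NaN) with ``n`` recorded.  Value columns keep their names;
    the result carries ``scaffold, start, end, length, short, n`` plus the
    aggregated value columns.
    """
    if report_window % unit_window != 0 or report_window // unit_window < 2:
        raise ConfigError(
            f"report window {report_window} is not an integer multiple (>=2) "
            f"of the unit window {unit_window}"
        )
    rgrid = make_window_grid(index, report_window)
    eligible = ~unit_grid["short"]
    if masked is not None:
        eligible &= ~masked
    mid = (unit_grid["start"] + unit_grid["end"]) // 2
    # clip midpoints into the scaffold (lifted windows near a target edge
    # can nominally extend past it)
    scaf_len = unit_grid["scaffold"].map(index.lengths)
    mid = np.minimum(mid.to_numpy(), scaf_len.to_numpy() - 1)
    from .core import scaffold_window_offsets

    offsets = scaffold_window_offsets(index, report_window)
    rid = unit_grid["scaffold"].map(offsets).to_numpy() + mid // report_window

    vals = unit_values.loc[eligible]
    rids = rid[eligible.to_numpy()]
    grouped = vals.groupby(rids).mean()
    n = pd.Series(rids).value_counts()
    out = rgrid.copy()
    out["n"] = n.reindex(out.index).fillna(0).astype(int)
    for col in unit_values.columns:
        out[col] = grouped[col].reindex(out.index)
    thin = out["n"] < min_contributing
    out.loc[thin, list(unit_values.columns)] = np.nan
    return out


def confidence_band(
    diffs: pd.Series,
    metric: str,
    level: float = 0.95,
    method: str = "quantile",
    min_windows: int = 20,
) -> Optional[ConfidenceBand]:
    """Genome-wide band for a window-difference distribution.

    ``quantile``: empirical (1−level)/2 and 1−(1−level)/2 percentiles.
    ``stddev``: mean ± z·SD with z the two-sided normal quantile.
    Returns None (with a warning) when fewer than ``min_windows``
    non-missing windows are available.
    """
    x = diffs.dropna().to_numpy()
    if x.size < min_windows:
        log.warning(
            "metric %s: only %d non-missing report windows (<%d); band omitted",
            metric, x.size, min_windows,
        )
        return None
    alpha = (1 - level) / 2
    if method == "quantile":
        low, high = np.percentile(x, [100 * alpha, 100 * (1 - alpha)])
    elif method == "stddev":
        from scipy.stats import norm  # local import: scipy not otherwise needed

        z = norm.ppf(1 - alpha)
        m, s = x.mean(), x.std(ddof=1)
        low, high = m - z * s, m + z * s
    else:
        raise ConfigError(f"unknown band method {method!r}")
    return ConfidenceBand(metric, float(low), float(high), method)


def flag_outlier_windows(
    diffs: pd.Series, band: Optional[ConfidenceBand]
) -> pd.Series:
    """Classify each window as none/high/low relative to the band."""
    out = pd.Series("none", index=diffs.index, dtype="object")
    if band is None:
        return out
    out[diffs > band.high] = "high"
    out[diffs < band.low] = "low"
    out[diffs.isna()] = "none"
    return out


def per_scaffold_summary(
    unit_diffs: Mapping[str, pd.Series],
    unit_grid: pd.DataFrame,
    index: GenomeIndex,
    masked: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Mean difference per scaffold for every metric, plus scaffold length.

    Uses unmasked, full-length unit windows; scaffolds with no eligible
    window are excluded (logged).
    """
    eligible = ~unit_grid["short"]
    if masked is not None:
        eligible &= ~masked
    scaf = unit_grid.loc[eligible, "scaffold"]
    out = pd.DataFrame(index=pd.Index(index.names, name="scaffold"))
    out["length"] = [index.lengths[n] for n in index.names]
    for metric, diffs in unit_diffs.items():
        out[metric] = diffs.loc[eligible.to_numpy()].groupby(scaf.to_numpy()).mean()
    covered = set(scaf.unique())
    dropped = [n for n in index.names if n not in covered]
    if dropped:
        log.info("per-scaffold summary: no eligible windows on %s", dropped)
        out = out.drop(index=dropped)
    return out


def per_sample_profiles(
    unit_values: Mapping[str, pd.DataFrame],
    unit_grid: pd.DataFrame,
    index: GenomeIndex,
    report_window: int,
    unit_window: int,
    masked: Optional[pd.Series] = None,
    min_contributing: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-sample value tracks at report-window resolution, per metric.

    These back the per-individual profile plot used to confirm that
    samples were sexed correctly: identical samples give identical
    tracks, and a mis-sexed sample clusters with the opposite role over
    sex-linked regions.
    """
    return {
        metric: aggregate_windows(
            vals, unit_grid, index, report_window, unit_window,
            masked=masked, min_contributing=min_contributing,
        )
        for metric, vals in unit_values.items()
    }


def per_chromosome_summary(
    aggregated: Mapping[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean ± SD of report-window differences per scaffold and metric.

    A scaffold with a single non-missing report window gets SD 0 (its n
    column makes the degeneracy visible).  Also returns the genome-wide
    median difference per metric (the dashed reference lines of the
    chromosome scatter plot).
    """
    frames = []
    medians = {}
    for metric, agg in aggregated.items():
        d = agg[["scaffold", "diff"]].dropna(subset=["diff"])
        g = d.groupby("scaffold")["diff"]
        df = pd.DataFrame(
            {"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()}
        )
        df["metric"] = metric
        frames.append(df.reset_index())
        medians[metric] = float(d["diff"].median()) if len(d) else float("nan")
    summary = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "mean", "sd", "n", "metric"]
    )
    return summary, pd.Series(medians)
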