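"""Mismatch-stratified read filtering and per-window genome coverage.

Coverage here is mean per-base depth over a window: the number of
reference bases covered by kept reads inside the window (from the CIGAR
aligned blocks, so deletions and clips contribute nothing) divided by the
window length.  A read spanning a window boundary contributes to each
window proportionally to its overlap, which is exactly equivalent to a
per-base pileup.

Three stringencies are scanned by default: strict (NM = 0), intermediate
(NM <= 2) and unfiltered (no mismatch gate).  All settings, including
"unfiltered", share the basic alignment gates (mapped, primary,
non-duplicate, mapping quality >= the configured floor); "unfiltered"
refers only to mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import GenomeIndex, MismatchSetting, scaffold_window_offsets
from .errors import DataError

log = logging.getLogger(__name__)

_EXCLUDE_FLAGS = (
    pysam.FUNMAP | pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FDUP | pysam.FQCFAIL
)


@dataclass
class FilterStats:
    """Per-BAM accounting of the read filter."""

    total: int = 0
    kept: dict[str, int] = field(default_factory=dict)
    aligned_bases: dict[str, int] = field(default_factory=dict)
    missing_nm: int = 0
    failed_gates: int = 0

    @property
    def missing_nm_fraction(self) -> float:
        return self.missing_nm / self.total if self.total else 0.0


def passes_alignment_filter(
    record: pysam.AlignedSegment,
    setting: MismatchSetting,
    min_mapq: int = 20,
    stats: Optional[FilterStats] = None,
) -> bool:
    """Gate a single alignment record under one mismatch setting.

    Unmapped, secondary, supplementary, duplicate or low-MAPQ records fail
    under every setting.  Bounded settings additionally require the NM tag
    (edit distance) to not exceed the threshold; records lacking NM are
    excluded from bounded settings and counted.
    """
    if record.flag & _EXCLUDE_FLAGS or record.mapping_quality < min_mapq:
        return False
    if setting.unbounded:
        return True
    try:
        nm = record.get_tag("NM")
    except KeyError:
        if stats is not None:
            stats.missing_nm += 1
        return False
    return nm <= setting.max_mismatches


def _add_block(depth_bases: np.ndarray, offset: int, w: int, scaf_len: int, bstart: int, bend: int) -> None:
    """Distribute an aligned block's bases over the windows it overlaps."""
    bend = min(bend, scaf_len)
    if bend <= bstart:
        return
    first = bstart // w
    last = (bend - 1) // w
    if first == last:
        depth_bases[offset + first] += bend - bstart
        return
    depth_bases[offset + first] += (first + 1) * w - bstart
    depth_bases[offset + last] += bend - last * w
    if last > first + 1:
        depth_bases[offset + first + 1 : offset + last] += w


def window_coverage(
    records: Iterable[pysam.AlignedSegment],
    grid: pd.DataFrame,
    index: GenomeIndex,
    window: int,
) -> np.ndarray:
    """Mean per-base depth per window from an already-filtered record stream.

    Records on scaffolds absent from the grid raise :class:`DataError`
    (index/BAM mismatch).
    """
    offsets = scaffold_window_offsets(index, window)
    depth_bases = np.zeros(len(grid), dtype=np.float64)
    lengths = index.lengths
    for r in records:
        name = r.reference_name
        if name not in offsets:
            raise DataError(f"read aligned to scaffold {name!r} absent from the genome index")
        off = offsets[name]
        L = lengths[name]
        for bstart, bend in r.get_blocks():
            _add_block(depth_bases, off, window, L, bstart, bend)
    return depth_bases / grid["length"].to_numpy()


def bam_window_coverage(
    bam_path: str,
    index: GenomeIndex,
    grid: pd.DataFrame,
    window: int,
    settings: Sequence[MismatchSetting],
    min_mapq: int = 20,
) -> tuple[dict[str, np.ndarray], FilterStats]:
    """Single-pass per-window raw depth for every mismatch setting.

    Returns ``{setting label: depth array aligned to grid}`` and filter
    statistics.  Mismatch thresholds nest, so the pass classifies each kept
    read by NM once and accumulates into every qualifying setting.
    """
    offsets = scaffold_window_offsets(index, window)
    lengths = index.lengths
    depth = {s.label: np.zeros(len(grid), dtype=np.float64) for s in settings}
    stats = FilterStats(kept={s.label: 0 for s in settings},
                        aligned_bases={s.label: 0 for s in settings})
    bounded = [s for s in settings if not s.unbounded]
    unbounded = [s for s in settings if s.unbounded]
    with pysam.AlignmentFile(bam_path) as bf:
        for r in bf:
            stats.total += 1
            if r.flag & _EXCLUDE_FLAGS or r.mapping_quality < min_mapq:
                stats.failed_gates += 1
                continue
            name = r.reference_name
            if name not in offsets:
                raise DataError(
                    f"{bam_path}: read aligned to scaffold {name!r} absent from the genome index"
                )
            nm = None
            if bounded:
                try:
                    nm = r.get_tag("NM")
                except KeyError:
                    stats.missing_nm += 1
            active = list(unbounded)
            if nm is not None:
                active += [s for s in bounded if nm <= s.max_mismatches]
            if not active:
                continue
            off = offsets[name]
            L = lengths[name]
            blocks = r.get_blocks()
            nbases = 0
            for bstart, bend in blocks:
                nbases += min(bend, L) - bstart
            for s in active:
                stats.kept[s.label] += 1
                stats.aligned_bases[s.label] += nbases
                arr = depth[s.label]
                for bstart, bend in blocks:
                    _add_block(arr, off, window, L, bstart, bend)
    wl = grid["length"].to_numpy()
    if stats.total and stats.missing_nm_fraction > 0.01:
        log.warning(
            "%s: %.1f%% of records lack the NM tag and were excluded from "
            "mismatch-bounded settings", bam_path, 100 * stats.missing_nm_fraction,
        )
    return {label: arr / wl for label, arr in depth.items()}, stats


def mask_outlier_windows(
    raw_unbounded: pd.DataFrame, mask_factor: float = 10.0
) -> pd.Series:
    """Mask extreme coverage outliers before between-sample normalization.

    A window is masked when, for any sample, its unfiltered depth exceeds
    ``mask_factor`` times that sample's genome-wide median unfiltered
    depth.  The mask applies to every mismatch setting of that window.
    """
    if raw_unbounded.empty:
        raise DataError("no windows to mask")
    masked = pd.Series(False, index=raw_unbounded.index)
    for col in raw_unbounded.columns:
        med = float(raw_unbounded[col].median())
        masked |= raw_unbounded[col] > mask_factor * med
    if masked.all():
        raise DataError("all windows masked as coverage outliers; input is degenerate")
    return masked


def normalize_coverage(table: pd.DataFrame, masked: pd.Series) -> pd.DataFrame:
    """Scale each sample's depths so the mean over unmasked windows is 1."""
    out = table.copy()
    keep = ~masked
    for col in table.columns:
        mean = float(table.loc[keep, col].mean())
        if mean == 0:
            raise DataError(f"sample {col!r}: zero mean coverage; cannot normalize")
        out[col] = table[col] / mean
    return out
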