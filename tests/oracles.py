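"""Independent brute-force oracles used to cross-check the pipeline.

Everything here deliberately avoids the implementation's interval
arithmetic: coverage is accumulated base by base, heterozygosity by
scanning every (site, window) pair, projections by enumerating every
base of a block.
"""

from __future__ import annotations

import numpy as np
import pysam


def pileup_coverage(
    bam_path: str,
    index,
    window: int,
    max_mismatches=None,
    min_mapq: int = 20,
) -> dict[str, np.ndarray]:
    """Per-window mean depth from a per-base depth array, per scaffold."""
    exclude = 0x4 | 0x100 | 0x800 | 0x400 | 0x200
    depth = {name: np.zeros(length, dtype=np.int64) for name, length in index.scaffolds}
    with pysam.AlignmentFile(bam_path) as bf:
        for r in bf:
            if r.flag & exclude or r.mapping_quality < min_mapq:
                continue
            if max_mismatches is not None:
                try:
                    if r.get_tag("NM") > max_mismatches:
                        continue
                except KeyError:
                    continue
            arr = depth[r.reference_name]
            for s, e in r.get_blocks():
                arr[s : min(e, len(arr))] += 1
    out = {}
    for name, length in index.scaffolds:
        means = []
        for s in range(0, length, window):
            e = min(s + window, length)
            means.append(depth[name][s:e].sum() / (e - s))
        out[name] = np.array(means)
    return out


def records_pileup(records, ref_lengths: dict[str, int], window: int) -> dict[str, np.ndarray]:
    """Same as above but over an in-memory, already-filtered record list."""
    depth = {name: np.zeros(length, dtype=np.int64) for name, length in ref_lengths.items()}
    for r in records:
        arr = depth[r.reference_name]
        for s, e in r.get_blocks():
            arr[s : min(e, len(arr))] += 1
    out = {}
    for name, length in ref_lengths.items():
        means = []
        for s in range(0, length, window):
            e = min(s + window, length)
            means.append(depth[name][s:e].sum() / (e - s))
        out[name] = np.array(means)
    return out


def het_window_counts(sites, sample: str, scaffold: str, length: int, window: int) -> np.ndarray:
    """Heterozygous-site count per window by scanning every site."""
    n = -(-length // window)
    counts = np.zeros(n, dtype=int)
    for _, row in sites.iterrows():
        if row["scaffold"] != scaffold or row[sample] != 1:
            continue
        counts[int(row["pos"]) // window] += 1
    return counts


def block_projection_table(block) -> dict[int, int]:
    """Query->target mapping of one block, enumerated base by base."""
    qs = range(block.qstart, block.qend)
    if block.strand == "+":
        ts = range(block.tstart, block.tend)
    else:
        ts = range(block.tend - 1, block.tstart - 1, -1)
    return dict(zip(qs, ts))


def n50(lengths) -> int:
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    return 0
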