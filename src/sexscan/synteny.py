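"""Whole-genome-alignment block maps and window liftover.

The map is a set of co-linear, gap-free blocks between the study-species
("query") assembly and a synteny-species ("target") assembly.  Two input
dialects are read: standard 21-column PSL (gapped alignments are expanded
into their exact co-linear blocks, never interpolated across gaps) and a
7-column TSV ``qname qstart qend tname tstart tend strand`` with 0-based
half-open coordinates on the query's forward strand.

A unit window is *anchored* when at least half of it (configurable) is
covered by blocks agreeing on one target scaffold; its value is then
re-keyed to the projection of its midpoint through the best-overlapping
block.  The anchoring rate — anchored windows over all unit windows — is
the headline liftover statistic of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomeIndex
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

BLOCK_COLUMNS = ["qname", "qstart", "qend", "tname", "tstart", "tend", "strand"]


@dataclass(frozen=True)
class SyntenyBlock:
    """One co-linear alignment block; query and target spans are equal length."""

    qname: str
    qstart: int
    qend: int
    tname: str
    tstart: int
    tend: int
    strand: str

    def __post_init__(self):
        if self.qend - self.qstart != self.tend - self.tstart:
            raise DataError(
                f"block {self.qname}:{self.qstart}-{self.qend} -> "
                f"{self.tname}:{self.tstart}-{self.tend}: unequal span lengths"
            )
        if self.strand not in "+-":
            raise DataError(f"bad strand {self.strand!r}")

    def project(self, qpos: int) -> int:
        """Project a query coordinate through the block (reversed on −)."""
        if not self.qstart <= qpos < self.qend:
            raise ValueError("position outside block")
        off = qpos - self.qstart
        if self.strand == "+":
            return self.tstart + off
        return self.tend - 1 - off


class SyntenyMap:
    """Indexed collection of synteny blocks."""

    def __init__(self, blocks: pd.DataFrame):
        missing = [c for c in BLOCK_COLUMNS if c not in blocks.columns]
        if missing:
            raise DataError(f"synteny map missing columns {missing}")
        self.blocks = blocks.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for qname, sub in self.blocks.groupby("qname"):
            tree = IntervalTree()
            for i, row in sub.iterrows():
                if row.qend > row.qstart:
                    tree.addi(int(row.qstart), int(row.qend), i)
            self._trees[str(qname)] = tree

    def __len__(self) -> int:
        return len(self.blocks)

    def block(self, i: int) -> SyntenyBlock:
        r = self.blocks.iloc[i]
        return SyntenyBlock(
            str(r.qname), int(r.qstart), int(r.qend),
            str(r.tname), int(r.tstart), int(r.tend), str(r.strand),
        )

    def overlapping(self, qname: str, start: int, end: int) -> list[int]:
        tree = self._trees.get(qname)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def target_index(self) -> GenomeIndex:
        """Target scaffold extents inferred from the blocks themselves."""
        if self.blocks.empty:
            raise DataError("cannot infer target index from an empty map")
        ext = self.blocks.groupby("tname")["tend"].max().sort_index()
        return GenomeIndex(list(ext.items()))

    def write_tsv(self, path: str | Path) -> None:
        self.blocks[BLOCK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _parse_tsv(path: str | Path) -> tuple[list[tuple], int]:
    rows, bad = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                parts = line.split()
            try:
                qname, qs, qe, tname, ts, te, strand = parts[:7]
                qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
                if strand not in "+-" or qe - qs != te - ts or qe <= qs:
                    raise ValueError
                rows.append((qname, qs, qe, tname, ts, te, strand))
            except (ValueError, IndexError):
                bad += 1
    return rows, bad


def _parse_psl(path: str | Path) -> tuple[list[tuple], int]:
    """Expand PSL records into co-linear blocks.

    For '-' strand records the per-block query starts are given on the
    reversed query sequence; they are converted back to forward-strand
    coordinates, with the target span aligned to the reversed query.
    """
    rows, bad = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            # skip blanks, comments and psLayout headers ("psLayout", "match ...", "-----")
            if not line or not line[0].isdigit():
                continue
            parts = line.split("\t")
            if len(parts) < 21:
                bad += 1
                continue
            try:
                strand = parts[8]
                qname, qsize = parts[9], int(parts[10])
                tname = parts[13]
                sizes = [int(x) for x in parts[18].rstrip(",").split(",")]
                qstarts = [int(x) for x in parts[19].rstrip(",").split(",")]
                tstarts = [int(x) for x in parts[20].rstrip(",").split(",")]
                if not (len(sizes) == len(qstarts) == len(tstarts) == int(parts[17])):
                    raise ValueError
                # strand field may be 1 or 2 chars (e.g. "+-" for translated)
                qstrand = strand[0]
                if qstrand not in "+-":
                    raise ValueError
                for size, qs, ts in zip(sizes, qstarts, tstarts):
                    if qstrand == "+":
                        rows.append((qname, qs, qs + size, tname, ts, ts + size, "+"))
                    else:
                        fqs = qsize - qs - size
                        rows.append((qname, fqs, fqs + size, tname, ts, ts + size, "-"))
            except (ValueError, IndexError):
                bad += 1
    return rows, bad


def parse_alignment_map(path: str | Path, dialect: str = "tsv") -> SyntenyMap:
    """Read a whole-genome-alignment block map (PSL or 7-column TSV)."""
    if dialect == "tsv":
        rows, bad = _parse_tsv(path)
    elif dialect == "psl":
        rows, bad = _parse_psl(path)
    else:
        raise ConfigError(f"unknown synteny map dialect {dialect!r}")
    total = len(rows) + bad
    if total and bad / total > 0.10:
        raise DataError(
            f"{path}: {bad}/{total} malformed lines in {dialect} map"
        )
    if bad:
        log.warning("%s: skipped %d malformed lines", path, bad)
    blocks = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    return SyntenyMap(blocks)


@dataclass(frozen=True)
class Anchor:
    tname: str
    tpos: int
    overlap_fraction: float
    block_index: int


def anchor_window(
    start: int,
    end: int,
    qname: str,
    smap: SyntenyMap,
    min_overlap: float = 0.5,
) -> Optional[Anchor]:
    """Anchor one window onto the target assembly, or return None.

    Blocks overlapping the window are grouped by target scaffold; the
    window anchors iff the majority scaffold's total overlap covers at
    least ``min_overlap`` of the window.  The midpoint is projected
    through the best-overlapping block of that scaffold (ties broken by
    larger block, then lexicographic target name), clamped into the block
    if the midpoint itself lies outside it.
    """
    idxs = smap.overlapping(qname, start, end)
    if not idxs:
        return None
    wlen = end - start
    per_target: dict[str, int] = {}
    best: dict[str, tuple] = {}
    for i in idxs:
        r = smap.blocks.iloc[i]
        ov = min(end, r.qend) - max(start, r.qstart)
        if ov <= 0:
            continue
        per_target[r.tname] = per_target.get(r.tname, 0) + ov
        key = (ov, r.qend - r.qstart, -i)
        if r.tname not in best or key > best[r.tname][0]:
            best[r.tname] = (key, i)
    if not per_target:
        return None
    # majority target: max overlap, ties by larger best block then name
    tname = min(
        per_target,
        key=lambda t: (-per_target[t], -(best[t][0][1]), t),
    )
    total_ov = per_target[tname]
    if total_ov < min_overlap * wlen:
        return None
    bi = best[tname][1]
    blk = smap.block(bi)
    mid = (start + end) // 2
    mid = min(max(mid, blk.qstart), blk.qend - 1)
    return Anchor(tname, blk.project(mid), total_ov / wlen, bi)


def liftover_table(
    unit_grid: pd.DataFrame,
    smap: SyntenyMap,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Anchor every unit window; return the anchor table and anchoring rate.

    The table is aligned to the unit grid with columns ``anchored, tname,
    tpos, overlap_fraction``.  Unanchored windows stay in the
    study-coordinate outputs but drop out of the synteny branch.  The
    anchoring rate is anchored / total unit windows.
    """
    n = len(unit_grid)
    anchored = np.zeros(n, dtype=bool)
    tname = np.full(n, "", dtype=object)
    tpos = np.full(n, -1, dtype=np.int64)
    frac = np.zeros(n, dtype=float)
    for i, (scaf, start, end) in enumerate(
        zip(unit_grid["scaffold"], unit_grid["start"], unit_grid["end"])
    ):
        a = anchor_window(int(start), int(end), str(scaf), smap, min_overlap)
        if a is not None:
            anchored[i] = True
            tname[i] = a.tname
            tpos[i] = a.tpos
            frac[i] = a.overlap_fraction
    table = pd.DataFrame(
        {"anchored": anchored, "tname": tname, "tpos": tpos, "overlap_fraction": frac},
        index=unit_grid.index,
    )
    rate = float(anchored.mean()) if n else 0.0
    return table, rate


def lifted_unit_grid(
    unit_grid: pd.DataFrame, anchors: pd.DataFrame, unit_window: int
) -> pd.DataFrame:
    """Re-key anchored unit windows to target coordinates.

    Each anchored window becomes a nominal unit window centred on its
    projected midpoint (clipped at the scaffold start), so downstream
    midpoint binning lands it in the right target report window.
    """
    keep = anchors["anchored"]
    g = unit_grid.loc[keep].copy()
    g["scaffold"] = anchors.loc[keep, "tname"].astype(object)
    mid = anchors.loc[keep, "tpos"].to_numpy()
    start = np.maximum(mid - unit_window // 2, 0)
    g["start"] = start
    g["end"] = start + (unit_grid.loc[keep, "length"].to_numpy())
    g["length"] = g["end"] - g["start"]
    return g
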