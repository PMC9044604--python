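"""Variant quality filtering, windowed heterozygosity and consensus genome.

Variants are expected to be called from the unfiltered alignments of all
samples against the study-species reference.  Only biallelic SNVs passing
conventional hard filters are kept; per-window heterozygosity is the count
of heterozygous genotypes divided by the full window length (the same
denominator for every sample, so sex contrasts are unbiased even though
callable-site variation is ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .core import GenomeIndex, scaffold_window_offsets
from .errors import DataError

log = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class FilteredVariantSet:
    """Biallelic SNVs surviving quality filtering.

    ``sites`` has columns ``scaffold, pos`` (0-based), ``ref, alt`` and one
    int8 genotype column per sample (0 hom_ref, 1 het, 2 hom_alt,
    -1 missing).  ``dropped`` counts records removed by reason.
    """

    sites: pd.DataFrame
    sample_ids: list[str]
    dropped: dict[str, int] = field(default_factory=dict)

    def het_matrix(self) -> np.ndarray:
        """Boolean (site x sample) matrix of heterozygous genotypes."""
        return (self.sites[self.sample_ids].to_numpy() == HET)


def _classify_genotype(gt: tuple, gq, dp, min_gq: float, min_dp: int) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    if gq is not None and gq < min_gq:
        return MISSING
    if dp is not None and dp < min_dp:
        return MISSING
    alleles = set(gt)
    if alleles == {0}:
        return HOM_REF
    if 0 in alleles:
        return HET
    return HET if len(alleles) > 1 else HOM_ALT


def filter_variants(
    vcf_path: str | Path,
    sample_ids: Sequence[str],
    min_site_qual: float = 30.0,
    min_genotype_qual: float = 20.0,
    min_depth: int = 3,
) -> FilteredVariantSet:
    """Quality-filter a multi-sample VCF down to biallelic SNVs.

    Sites with QUAL below ``min_site_qual`` are dropped; genotypes with
    GQ < ``min_genotype_qual`` or DP < ``min_depth`` are set missing.
    Indels and multiallelic records are dropped and counted.
    """
    dropped = {"indel_or_sv": 0, "multiallelic": 0, "low_qual": 0}
    rows: list[tuple] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        have = set(vf.header.samples)
        missing = [s for s in sample_ids if s not in have]
        if missing:
            raise DataError(f"samples absent from VCF header: {missing}")
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                dropped["multiallelic"] += 1 if len(alts) > 1 else 0
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                dropped["indel_or_sv"] += 1
                continue
            if rec.qual is None or rec.qual < min_site_qual:
                dropped["low_qual"] += 1
                continue
            genos = []
            for sid in sample_ids:
                call = rec.samples[sid]
                genos.append(
                    _classify_genotype(
                        call.get("GT"), call.get("GQ"), call.get("DP"),
                        min_genotype_qual, min_depth,
                    )
                )
            rows.append((rec.chrom, rec.pos - 1, rec.ref, alts[0], *genos))
    sites = pd.DataFrame(
        rows, columns=["scaffold", "pos", "ref", "alt", *sample_ids]
    )
    if not sites.empty:
        sites = sites.sort_values(["scaffold", "pos"], kind="stable").reset_index(drop=True)
        for sid in sample_ids:
            sites[sid] = sites[sid].astype(np.int8)
    log.info("variant filter: kept %d sites, dropped %s", len(sites), dropped)
    return FilteredVariantSet(sites, list(sample_ids), dropped)


def window_heterozygosity(
    variants: FilteredVariantSet,
    grid: pd.DataFrame,
    index: GenomeIndex,
    window: int,
) -> pd.DataFrame:
    """Heterozygous genotypes per bp for each (window, sample).

    Missing genotypes contribute nothing; the denominator is the full
    window length.
    """
    out = pd.DataFrame(
        0.0, index=grid.index, columns=list(variants.sample_ids)
    )
    if variants.sites.empty:
        return out
    offsets = scaffold_window_offsets(index, window)
    sites = variants.sites
    unknown = set(sites["scaffold"]) - set(offsets)
    if unknown:
        raise DataError(f"variants on scaffolds absent from the genome index: {sorted(unknown)}")
    off = sites["scaffold"].map(offsets).to_numpy(dtype=np.int64)
    wid = off + sites["pos"].to_numpy(dtype=np.int64) // window
    het = variants.het_matrix()
    counts = np.zeros((len(grid), het.shape[1]), dtype=np.int64)
    np.add.at(counts, wid, het.astype(np.int64))
    wl = grid["length"].to_numpy()[:, None]
    out.iloc[:, :] = counts / wl
    return out


def genomewide_heterozygosity(
    variants: FilteredVariantSet, index: GenomeIndex
) -> pd.Series:
    """Per-sample heterozygosity as a percentage of the genome length.

    Values >= 1% warrant caution: at such diversity the sex-linked signal
    can drown in background heterozygosity.
    """
    total = index.total_length
    if variants.sites.empty:
        return pd.Series(0.0, index=list(variants.sample_ids))
    het_counts = variants.het_matrix().sum(axis=0)
    return pd.Series(100.0 * het_counts / total, index=list(variants.sample_ids))


def build_consensus_genome(
    reference: str | Path,
    variants: FilteredVariantSet,
    out_path: str | Path,
    line_width: int = 60,
) -> dict[str, int]:
    """Write a consensus FASTA incorporating majority alternate alleles.

    At each kept site the alternate base replaces the reference iff the
    alternate-allele count over all genotypes exceeds the reference-allele
    count (het contributes one of each, hom two, missing none); ties keep
    the reference.  Scaffold names, order and lengths are preserved.
    Returns ``{scaffold: substitutions made}``.
    """
    import pyfaidx

    fa = pyfaidx.Fasta(str(reference))
    sites = variants.sites
    gmat = sites[variants.sample_ids].to_numpy() if not sites.empty else None
    substituted: dict[str, int] = {}
    with open(out_path, "w") as out:
        for name in fa.keys():
            seq = np.frombuffer(str(fa[name][:]).upper().encode(), dtype="S1").copy()
            nsub = 0
            if gmat is not None:
                here = sites["scaffold"].to_numpy() == name
                if here.any():
                    pos = sites.loc[here, "pos"].to_numpy()
                    refs = sites.loc[here, "ref"].to_numpy()
                    alts = sites.loc[here, "alt"].to_numpy()
                    g = gmat[here]
                    alt_count = (g == HET).sum(axis=1) + 2 * (g == HOM_ALT).sum(axis=1)
                    ref_count = (g == HET).sum(axis=1) + 2 * (g == HOM_REF).sum(axis=1)
                    fasta_bases = seq[pos].astype("U1")
                    bad = fasta_bases != refs
                    if bad.any():
                        i = int(np.argmax(bad))
                        raise DataError(
                            f"reference allele mismatch at {name}:{int(pos[i]) + 1}: "
                            f"VCF says {refs[i]!r}, FASTA has {fasta_bases[i]!r}"
                        )
                    swap = alt_count > ref_count
                    seq[pos[swap]] = np.char.encode(alts[swap].astype("U1"))
                    nsub = int(swap.sum())
            substituted[name] = nsub
            out.write(f">{name}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), line_width):
                out.write(s[i : i + line_width] + "\n")
    pyfaidx.Faidx(str(out_path), rebuild=True)
    return substituted
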