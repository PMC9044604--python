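"""Synthetic WGS fixtures: reference FASTA, per-sample BAMs, VCF, synteny maps.

The generator fabricates the classic sex-linkage scenarios directly as
aligned data, so the whole pipeline is testable without running an
aligner or variant caller:

* ``autosomal`` / ``PAR`` regions are symmetric between sexes.
* ``low_diff`` sex-linked regions: the heterogametic sex's Y/W-derived
  read half carries a few mismatches per read (it still maps), so
  coverage looks equal without filtering but drops to ~half under a
  0-mismatch filter, while gametolog divergence shows up as excess
  heterozygosity.
* ``high_diff`` regions: a fraction ``degeneration`` of the Y/W copy is
  gone entirely; the remainder maps only with many mismatches.  With
  full degeneration the heterogametic sex sits at half coverage under
  every mismatch setting and shows no excess heterozygosity (the X/Z is
  hemizygous there).

Reads are written as already-aligned, coordinate-sorted BAM records with
synthetic NM tags (and a sprinkling of duplicates, MAPQ-0 multimappers
and NM-less records), exercising the exact filter path the pipeline uses
on real alignments.  All randomness flows from one seed; per-sample
substreams are derived by stable hashing of the sample id.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import FEMALE, MALE, GenomeIndex, role_for
from .errors import ConfigError

AUTOSOMAL = "autosomal"
LOW_DIFF = "low_diff_sexlinked"
HIGH_DIFF = "high_diff_sexlinked"
PAR = "PAR"

#: background per-read edit-distance rate (Poisson mean per read)
BACKGROUND_NM = 0.15
#: fraction of reads flagged as PCR duplicates / MAPQ-0 multimappers
DUP_FRACTION = 0.03
MAPQ0_FRACTION = 0.02
#: fraction of reads written without an NM tag (kept below the 1% warning)
NO_NM_FRACTION = 0.002
#: genotype-quality dropout (GQ 10 < default 20 floor) in the simulated VCF
LOW_GQ_FRACTION = 0.03


@dataclass(frozen=True)
class RegionSpec:
    """A typed genomic interval driving the simulated sex signal."""

    scaffold: str
    start: int
    end: int
    klass: str
    divergence: float = 0.0  # expected gametolog mismatches per 100 bp read
    degeneration: float = 0.0  # fraction of the Y/W copy absent
    het_rate: Optional[float] = None  # per-bp per-sample background het rate

    def __post_init__(self):
        if self.klass not in (AUTOSOMAL, LOW_DIFF, HIGH_DIFF, PAR):
            raise ConfigError(f"unknown region class {self.klass!r}")
        if self.divergence < 0 or not 0 <= self.degeneration <= 1:
            raise ConfigError("divergence must be >=0 and degeneration in [0,1]")
        if self.start < 0 or self.end <= self.start:
            raise ConfigError("bad region interval")

    @property
    def sexlinked(self) -> bool:
        return self.klass in (LOW_DIFF, HIGH_DIFF)


@dataclass(frozen=True)
class SimSample:
    id: str
    sex: str
    depth: float


@dataclass
class SimScenario:
    """Full specification of one simulated study."""

    scaffolds: list[tuple[str, int]]
    regions: list[RegionSpec]
    samples: list[SimSample]
    system: str = "XY"
    read_length: int = 100
    het_rate: float = 0.001
    seed: int = 0
    unit_window: int = 5000
    report_window: int = 100_000

    def __post_init__(self):
        if any(s.depth <= 0 for s in self.samples):
            raise ConfigError("sample depths must be positive")
        index = self.index
        seen: dict[str, list[tuple[int, int]]] = {}
        for r in self.regions:
            if r.scaffold not in index.lengths:
                raise ConfigError(f"region on unknown scaffold {r.scaffold!r}")
            if r.end > index.lengths[r.scaffold]:
                raise ConfigError(f"region {r} exceeds scaffold length")
            for s, e in seen.setdefault(r.scaffold, []):
                if r.start < e and s < r.end:
                    raise ConfigError(f"overlapping regions on {r.scaffold}")
            seen[r.scaffold].append((r.start, r.end))

    @property
    def index(self) -> GenomeIndex:
        return GenomeIndex(self.scaffolds)

    def segments(self, scaffold: str) -> list[RegionSpec]:
        """Explicit regions plus autosomal gap-fill covering the scaffold."""
        L = self.index.lengths[scaffold]
        regs = sorted(
            (r for r in self.regions if r.scaffold == scaffold), key=lambda r: r.start
        )
        out, cur = [], 0
        for r in regs:
            if r.start > cur:
                out.append(RegionSpec(scaffold, cur, r.start, AUTOSOMAL))
            out.append(r)
            cur = r.end
        if cur < L:
            out.append(RegionSpec(scaffold, cur, L, AUTOSOMAL))
        return out

    def sample_rng(self, sample_id: str, stream: str) -> np.random.Generator:
        key = zlib.crc32(f"{sample_id}/{stream}".encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


def simulate_reference(scenario: SimScenario, out_fasta: str | Path) -> GenomeIndex:
    """Random-base scaffolds of the specified lengths (seed-deterministic)."""
    rng = scenario.sample_rng("__reference__", "bases")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(out_fasta, "w") as fh:
        for name, length in scenario.scaffolds:
            fh.write(f">{name}\n")
            seq = bases[rng.integers(0, 4, length)].tobytes().decode()
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(out_fasta), rebuild=True)
    return scenario.index


def _region_read_plan(
    seg: RegionSpec, heterogametic: bool, depth: float, rl: int, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """(expected read count, NM Poisson mean) components for one segment."""
    L = seg.end - seg.start
    base = L * depth / rl
    if not heterogametic or not seg.sexlinked:
        return [(base, BACKGROUND_NM)]
    # heterogametic sample on a sex-linked segment: X/Z half + surviving Y/W half
    y_fraction = 1.0 - seg.degeneration
    return [
        (base / 2, BACKGROUND_NM),
        (base / 2 * y_fraction, BACKGROUND_NM + seg.divergence * rl / 100.0),
    ]


def simulate_alignments(
    scenario: SimScenario, sample: SimSample, out_bam: str | Path
) -> int:
    """Write one coordinate-sorted, indexed BAM with NM tags; returns read count."""
    rl = scenario.read_length
    role = role_for(scenario.system, sample.sex)
    heterogametic = role == "heterogametic"
    rng = scenario.sample_rng(sample.id, "reads")
    index = scenario.index
    header = pysam.AlignmentHeader.from_references(
        [n for n, _ in scenario.scaffolds], [l for _, l in scenario.scaffolds]
    )
    total = 0
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bf:
        for ref_id, (name, length) in enumerate(scenario.scaffolds):
            pos_parts, nm_parts = [], []
            for seg in scenario.segments(name):
                lo = seg.start
                hi = min(seg.end, length - rl)
                if hi <= lo:
                    continue
                for expected, nm_mean in _region_read_plan(
                    seg, heterogametic, sample.depth, rl, rng
                ):
                    n = rng.poisson(expected * (hi - lo) / (seg.end - seg.start))
                    if n == 0:
                        continue
                    pos_parts.append(rng.integers(lo, hi, n))
                    nm_parts.append(rng.poisson(nm_mean, n))
            if not pos_parts:
                continue
            pos = np.concatenate(pos_parts)
            nm = np.concatenate(nm_parts)
            order = np.argsort(pos, kind="stable")
            pos, nm = pos[order], nm[order]
            n = len(pos)
            dup = rng.random(n) < DUP_FRACTION
            mapq0 = rng.random(n) < MAPQ0_FRACTION
            no_nm = rng.random(n) < NO_NM_FRACTION
            for i in range(n):
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample.id}.{name}.{i}"
                a.flag = 1024 if dup[i] else 0
                a.reference_id = ref_id
                a.reference_start = int(pos[i])
                a.mapping_quality = 0 if mapq0[i] else 60
                a.cigartuples = [(0, rl)]
                if not no_nm[i]:
                    a.set_tag("NM", int(nm[i]))
                bf.write(a)
            total += n
    pysam.index(str(out_bam))
    return total


def _draw_genotypes(
    rng: np.random.Generator, n: int, hemizygous: bool
) -> np.ndarray:
    """Population-site genotype codes (0 hom_ref / 1 het / 2 hom_alt)."""
    if hemizygous:
        return np.where(rng.random(n) < 0.2, 2, 0)
    u = rng.random(n)
    g = np.zeros(n, dtype=np.int8)
    g[u < 0.5] = 1
    g[u >= 0.9] = 2
    return g


def simulate_variants(
    scenario: SimScenario, reference: str | Path, out_vcf: str | Path
) -> int:
    """Write a multi-sample VCF realizing the scenario's heterozygosity model.

    Population SNPs give every sample the background het rate; gametolog
    divergence adds heterogametic-only het sites in low-differentiation
    regions (scaled down by degeneration in high-differentiation ones);
    fully degenerate regions leave the heterogametic sex hemizygous and
    het-free.  A small admixture of indel, multiallelic and low-quality
    records exercises the quality filter.  Returns the site count.
    """
    import pyfaidx

    fa = pyfaidx.Fasta(str(reference))
    rng = scenario.sample_rng("__variants__", "sites")
    roles = {s.id: role_for(scenario.system, s.sex) for s in scenario.samples}
    het_ids = [s.id for s in scenario.samples if roles[s.id] == "heterogametic"]
    sample_ids = [s.id for s in scenario.samples]
    depth = {s.id: s.depth for s in scenario.samples}
    other = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "A"}
    lines = []
    nsites = 0
    for name, length in scenario.scaffolds:
        seq = str(fa[name][:]).upper()
        records: dict[int, tuple] = {}
        for seg in scenario.segments(name):
            L = seg.end - seg.start
            bg = seg.het_rate if seg.het_rate is not None else scenario.het_rate
            # population sites shared by all samples (each sample het w.p. 0.5)
            n_pop = rng.poisson(2 * bg * L)
            pop_pos = rng.integers(seg.start, seg.end, n_pop) if n_pop else np.array([], int)
            hemi = seg.klass == HIGH_DIFF and seg.degeneration >= 1.0
            for p in np.unique(pop_pos):
                genos = {}
                for sid in sample_ids:
                    hz = hemi and roles[sid] == "heterogametic"
                    genos[sid] = int(_draw_genotypes(rng, 1, hz)[0])
                records[int(p)] = ("pop", genos)
            # gametolog-divergence sites: het in the heterogametic sex only
            if seg.sexlinked:
                excess = seg.divergence / 100.0 * 0.5 * (1.0 - seg.degeneration)
                n_div = rng.poisson(excess * L)
                div_pos = rng.integers(seg.start, seg.end, n_div) if n_div else np.array([], int)
                for p in np.unique(div_pos):
                    if int(p) in records:
                        continue
                    genos = {sid: (1 if sid in het_ids else 0) for sid in sample_ids}
                    records[int(p)] = ("div", genos)
        # junk records dropped by the quality filter
        n_junk = rng.poisson(0.025 * max(len(records), 1))
        junk_pos = rng.integers(0, length, n_junk) if n_junk else np.array([], int)
        junk_kinds = rng.integers(0, 3, n_junk)
        for p, kind in zip(junk_pos, junk_kinds):
            if int(p) in records:
                continue
            records[int(p)] = (("indel", "multi", "lowqual")[kind], None)
        for p in sorted(records):
            kind, genos = records[p]
            ref = seq[p]
            if ref == "N":
                continue
            alt = other[ref]
            qual = float(rng.uniform(40, 200))
            if kind == "indel":
                alt = ref + "AT"
            elif kind == "multi":
                alt = f"{alt},{other[alt]}"
            elif kind == "lowqual":
                qual = float(rng.uniform(2, 25))
            fields = [name, str(p + 1), ".", ref, alt, f"{qual:.1f}", "PASS", ".", "GT:GQ:DP"]
            for sid in sample_ids:
                g = genos[sid] if genos is not None else 0
                gt = ("0/0", "0/1", "1/1")[g]
                gq = 10 if rng.random() < LOW_GQ_FRACTION else 99
                dp = int(rng.poisson(depth[sid]))
                fields.append(f"{gt}:{gq}:{dp}")
            lines.append("\t".join(fields))
            nsites += 1
    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in scenario.scaffolds:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return nsites


def simulate_synteny_map(
    index: GenomeIndex,
    mode: str,
    out_path: str | Path,
    seed: int = 0,
    keep_fraction: float = 0.5,
    block_bp: int = 5000,
    target_prefix: str = "syn_",
) -> None:
    """Write a TSV block map onto a fabricated synteny-species assembly.

    ``identity``: one forward block per scaffold onto an identically-sized
    target scaffold (named with ``target_prefix``).  ``shuffled``: the
    scaffolds are permuted and concatenated onto two long target scaffolds
    with random strands, emulating a fragmented-to-contiguous liftover.
    ``partial``: identity tiling split into ``block_bp`` blocks of which a
    random ``keep_fraction`` survives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(mode.encode())]))
    rows = []
    if mode == "identity":
        for name, length in index.scaffolds:
            rows.append((name, 0, length, target_prefix + name, 0, length, "+"))
    elif mode == "partial":
        for name, length in index.scaffolds:
            for s in range(0, length, block_bp):
                e = min(s + block_bp, length)
                if rng.random() < keep_fraction:
                    rows.append((name, s, e, target_prefix + name, s, e, "+"))
    elif mode == "shuffled":
        order = rng.permutation(len(index.scaffolds))
        targets = [target_prefix + "A", target_prefix + "B"]
        cursor = {t: 0 for t in targets}
        for k, i in enumerate(order):
            name, length = index.scaffolds[i]
            t = targets[k % 2]
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((name, 0, length, t, cursor[t], cursor[t] + length, strand))
            cursor[t] += length
    else:
        raise ConfigError(f"unknown synteny map mode {mode!r}")
    with open(out_path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# Scenario presets: desk-scale versions of the canonical differentiation
# regimes.  Sizes are chosen so a full pipeline run takes well under five
# minutes on one CPU while leaving >=99 report windows for the 95% band.
# ---------------------------------------------------------------------------

def preset_scenario(name: str, seed: int = 0) -> SimScenario:
    two_per_sex = [
        SimSample("F1", FEMALE, 10.0),
        SimSample("F2", FEMALE, 11.0),
        SimSample("M1", MALE, 9.0),
        SimSample("M2", MALE, 10.5),
    ]
    one_per_sex = [SimSample("F1", FEMALE, 10.0), SimSample("M1", MALE, 9.0)]
    if name == "null":
        return SimScenario(
            scaffolds=[(f"chr{i}", 1_000_000) for i in range(1, 6)],
            regions=[],
            samples=one_per_sex,
            seed=seed,
            report_window=25_000,
        )
    autosomes = [(f"chr{i}", 2_400_000) for i in range(1, 5)]
    if name == "fig1b":
        scaffolds = autosomes + [(f"sl{i}", 80_000) for i in range(1, 4)]
        regions = [
            RegionSpec(f"sl{i}", 0, 80_000, LOW_DIFF, divergence=3.0)
            for i in range(1, 4)
        ]
    elif name in ("fig1c", "fig1d"):
        deg = 1.0 if name == "fig1d" else 0.3
        scaffolds = autosomes + [("scafZ", 400_000)]
        regions = [
            RegionSpec("scafZ", 0, 200_000, HIGH_DIFF, divergence=8.0, degeneration=deg),
            RegionSpec("scafZ", 200_000, 400_000, PAR),
        ]
    else:
        raise ConfigError(f"unknown preset {name!r} (expected fig1b|fig1c|fig1d|null)")
    return SimScenario(
        scaffolds=scaffolds, regions=regions, samples=two_per_sex, seed=seed,
        report_window=100_000,
    )


def truly_sexlinked_report_windows(scenario: SimScenario) -> list[tuple[str, int, int]]:
    """Report windows lying entirely inside a sex-linked region (the truth set)."""
    rw = scenario.report_window
    out = []
    for r in scenario.regions:
        if not r.sexlinked:
            continue
        L = scenario.index.lengths[r.scaffold]
        for s in range(0, L, rw):
            e = min(s + rw, L)
            if s >= r.start and e <= r.end:
                out.append((r.scaffold, s, e))
    return out


def simulate_all(
    scenario: SimScenario,
    outdir: str | Path,
    synteny_mode: Optional[str] = None,
    keep_fraction: float = 0.5,
) -> dict:
    """Materialize a scenario: FASTA, BAMs, VCF, optional map, run config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = outdir / "reference.fa"
    simulate_reference(scenario, ref)
    bams = {}
    for s in scenario.samples:
        bam = outdir / f"{s.id}.bam"
        simulate_alignments(scenario, s, bam)
        bams[s.id] = str(bam)
    vcf = outdir / "variants.vcf"
    simulate_variants(scenario, ref, vcf)
    map_path = None
    if synteny_mode is not None:
        map_path = outdir / f"map_{synteny_mode}.tsv"
        simulate_synteny_map(
            scenario.index, synteny_mode, map_path,
            seed=scenario.seed, keep_fraction=keep_fraction,
        )
    config = {
        "system": scenario.system,
        "reference": "reference.fa",
        "vcf": "variants.vcf",
        "samples": [
            {"id": s.id, "sex": s.sex, "bam": f"{s.id}.bam"} for s in scenario.samples
        ],
        "unit_window": scenario.unit_window,
        "report_windows": [scenario.report_window],
        "seed": scenario.seed,
        "output_dir": "results",
    }
    if map_path is not None:
        config["synteny_map"] = os.path.basename(map_path)
        config["synteny_dialect"] = "tsv"
    import yaml

    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return {
        "reference": str(ref),
        "bams": bams,
        "vcf": str(vcf),
        "map": str(map_path) if map_path else None,
        "config": str(cfg_path),
    }
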