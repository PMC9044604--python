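"""Coordinate system, sample metadata, window grid and run configuration.

Internal coordinates are 0-based half-open everywhere; VCF positions
(1-based) are converted on read, and output tables print 1-based inclusive
coordinates (documented in the table README).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

MALE = "male"
FEMALE = "female"
HETEROGAMETIC = "heterogametic"
HOMOGAMETIC = "homogametic"

#: Mismatch-threshold presets applied to the coverage branch.  ``None``
#: means unbounded ("unfiltered": no mismatch-based read removal).  The
#: heterozygosity branch always uses the unbounded alignments.
UNFILTERED_LABEL = "unfiltered"


@dataclass(frozen=True)
class MismatchSetting:
    """A read-filtering stringency: keep reads with NM <= ``max_mismatches``.

    ``max_mismatches=None`` disables the mismatch gate entirely.
    """

    label: str
    max_mismatches: Optional[int]

    @property
    def unbounded(self) -> bool:
        return self.max_mismatches is None

    def __post_init__(self) -> None:
        if self.max_mismatches is not None and self.max_mismatches < 0:
            raise ConfigError(f"negative mismatch threshold for setting {self.label!r}")


def default_mismatch_settings() -> list[MismatchSetting]:
    """Strict (0 mismatches), intermediate (<=2) and unfiltered."""
    return [
        MismatchSetting(UNFILTERED_LABEL, None),
        MismatchSetting("2mm", 2),
        MismatchSetting("0mm", 0),
    ]


class GenomeIndex:
    """Ordered scaffold names and lengths defining the coordinate space.

    Built from a FASTA index (``.fai`` dialect: name and length in the
    first two columns), preserving file order.
    """

    def __init__(self, scaffolds: Sequence[tuple[str, int]]):
        names = [n for n, _ in scaffolds]
        if not names:
            raise ConfigError("genome index contains no scaffolds")
        if len(set(names)) != len(names):
            raise ConfigError("duplicate scaffold names in genome index")
        for name, length in scaffolds:
            if length < 1:
                raise ConfigError(f"scaffold {name!r} has non-positive length {length}")
        self.scaffolds: list[tuple[str, int]] = [(n, int(l)) for n, l in scaffolds]
        self.lengths: dict[str, int] = dict(self.scaffolds)

    @classmethod
    def from_fai(cls, path: str | Path) -> "GenomeIndex":
        scaffolds = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split("\t")
                scaffolds.append((parts[0], int(parts[1])))
        return cls(scaffolds)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        """Index the FASTA (creating ``.fai`` if needed) and load it."""
        import pyfaidx

        fai = str(path) + ".fai"
        if not os.path.exists(fai):
            pyfaidx.Faidx(str(path))
        return cls.from_fai(fai)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.scaffolds]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self.scaffolds == other.scaffolds

    def subset(self, names: Sequence[str]) -> "GenomeIndex":
        wanted = set(names)
        kept = [(n, l) for n, l in self.scaffolds if n in wanted]
        missing = wanted - {n for n, _ in kept}
        if missing:
            raise ConfigError(f"scaffolds not in index: {sorted(missing)}")
        return GenomeIndex(kept)


@dataclass
class Sample:
    """One sequenced individual with its sex label and alignment file."""

    id: str
    sex_label: str
    alignment_path: Optional[str] = None
    role: Optional[str] = None  # assigned by validate_sample_sheet

    def __post_init__(self) -> None:
        if self.sex_label not in (MALE, FEMALE):
            raise ConfigError(
                f"sample {self.id!r}: unknown sex label {self.sex_label!r} "
                f"(expected {MALE!r} or {FEMALE!r})"
            )


def role_for(system: str, sex_label: str) -> str:
    """Pure mapping (system, sex) -> role.

    XY: males are heterogametic; ZW: females are heterogametic.
    """
    if system not in ("XY", "ZW"):
        raise ConfigError(f"unknown heterogamety system {system!r}")
    het_sex = MALE if system == "XY" else FEMALE
    return HETEROGAMETIC if sex_label == het_sex else HOMOGAMETIC


@dataclass
class RunConfig:
    """Everything a run needs; loadable from a YAML file."""

    system: str
    samples: list[Sample]
    reference: Optional[str] = None
    vcf: Optional[str] = None
    unit_window: int = 5000
    report_windows: list[int] = field(default_factory=lambda: [1_000_000])
    mismatch_settings: list[MismatchSetting] = field(default_factory=default_mismatch_settings)
    synteny_map: Optional[str] = None
    synteny_dialect: str = "tsv"
    chromosomes: list[str] = field(default_factory=list)
    highlight: list[str] = field(default_factory=list)
    seed: int = 1
    output_dir: str = "sexscan_out"
    # knobs with documented defaults
    min_mapq: int = 20
    mask_factor: float = 10.0
    min_site_qual: float = 30.0
    min_genotype_qual: float = 20.0
    min_depth: int = 3
    band_method: str = "quantile"  # or "stddev"
    anchor_min_overlap: float = 0.5
    min_contributing: int = 5

    def validate(self) -> None:
        if self.system not in ("XY", "ZW"):
            raise ConfigError(f"system must be XY or ZW, got {self.system!r}")
        if self.unit_window < 1000:
            raise ConfigError("unit_window must be >= 1000 bp")
        if not self.report_windows:
            raise ConfigError("at least one report window size is required")
        for rw in self.report_windows:
            if rw % self.unit_window != 0 or rw // self.unit_window < 2:
                raise ConfigError(
                    f"report window {rw} must be an integer multiple (>=2) of "
                    f"the {self.unit_window} bp unit window"
                )
        if not self.mismatch_settings:
            raise ConfigError("mismatch_settings must be non-empty")
        labels = [s.label for s in self.mismatch_settings]
        if len(set(labels)) != len(labels):
            raise ConfigError("mismatch setting labels must be unique")
        if not any(s.unbounded for s in self.mismatch_settings):
            # the heterozygosity branch always runs on the unbounded alignments
            self.mismatch_settings.insert(0, MismatchSetting(UNFILTERED_LABEL, None))
        if self.band_method not in ("quantile", "stddev"):
            raise ConfigError(f"unknown band method {self.band_method!r}")
        if not 0 < self.anchor_min_overlap <= 1:
            raise ConfigError("anchor_min_overlap must be in (0, 1]")

    @property
    def unbounded_setting(self) -> MismatchSetting:
        return next(s for s in self.mismatch_settings if s.unbounded)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str = ".") -> "RunConfig":
        def _path(p):
            if p is None:
                return None
            p = str(p)
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        try:
            samples = [
                Sample(str(s["id"]), str(s["sex"]), _path(s.get("bam")))
                for s in raw.get("samples", [])
            ]
        except KeyError as exc:
            raise ConfigError(f"sample sheet entry missing field {exc}") from exc
        settings = raw.get("mismatch_settings")
        if settings is None:
            mm = default_mismatch_settings()
        else:
            mm = [MismatchSetting(str(s["label"]), s.get("max_mismatches")) for s in settings]
        cfg = cls(
            system=str(raw.get("system", "XY")),
            samples=samples,
            reference=_path(raw.get("reference")),
            vcf=_path(raw.get("vcf")),
            unit_window=int(raw.get("unit_window", 5000)),
            report_windows=[int(x) for x in raw.get("report_windows", [1_000_000])],
            mismatch_settings=mm,
            synteny_map=_path(raw.get("synteny_map")),
            synteny_dialect=str(raw.get("synteny_dialect", "tsv")),
            chromosomes=[str(x) for x in raw.get("chromosomes", [])],
            highlight=[str(x) for x in raw.get("highlight", [])],
            seed=int(raw.get("seed", 1)),
            output_dir=_path(raw.get("output_dir", "sexscan_out")),
            min_mapq=int(raw.get("min_mapq", 20)),
            mask_factor=float(raw.get("mask_factor", 10.0)),
            min_site_qual=float(raw.get("min_site_qual", 30.0)),
            min_genotype_qual=float(raw.get("min_genotype_qual", 20.0)),
            min_depth=int(raw.get("min_depth", 3)),
            band_method=str(raw.get("band_method", "quantile")),
            anchor_min_overlap=float(raw.get("anchor_min_overlap", 0.5)),
            min_contributing=int(raw.get("min_contributing", 5)),
        )
        cfg.validate()
        return cfg


def make_window_grid(index: GenomeIndex, window: int) -> pd.DataFrame:
    """Tile every scaffold with half-open windows of ``window`` bp.

    The last window of a scaffold may be shorter; windows shorter than half
    the nominal size are flagged ``short`` (excluded from aggregation and
    interval estimation downstream).  Returns a DataFrame with columns
    ``scaffold, start, end, length, short`` indexed by window id.
    """
    if window < 1:
        raise ConfigError("window size must be >= 1 bp")
    if len(index) == 0:
        raise ConfigError("empty genome index")
    scaffolds, starts, ends = [], [], []
    for name, length in index.scaffolds:
        s = np.arange(0, length, window, dtype=np.int64)
        e = np.minimum(s + window, length)
        scaffolds.extend([name] * len(s))
        starts.append(s)
        ends.append(e)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    grid = pd.DataFrame(
        {
            "scaffold": pd.Series(scaffolds, dtype="object"),
            "start": start,
            "end": end,
        }
    )
    grid["length"] = grid["end"] - grid["start"]
    grid["short"] = grid["length"] < window / 2
    grid.index.name = "window_id"
    return grid


def scaffold_window_offsets(index: GenomeIndex, window: int) -> dict[str, int]:
    """First window id of each scaffold in the grid built by make_window_grid."""
    offsets = {}
    acc = 0
    for name, length in index.scaffolds:
        offsets[name] = acc
        acc += -(-length // window)  # ceil division
    return offsets


def validate_sample_sheet(samples: Sequence[Sample], config: RunConfig) -> list[Sample]:
    """Assign roles, check both roles present and alignment files usable."""
    if not samples:
        raise ConfigError("sample sheet is empty")
    ids = [s.id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate sample ids: {dupes}")
    for s in samples:
        s.role = role_for(config.system, s.sex_label)
        if s.alignment_path is not None:
            if not os.path.exists(s.alignment_path):
                raise ConfigError(f"sample {s.id!r}: alignment file not found: {s.alignment_path}")
            if not (
                os.path.exists(s.alignment_path + ".bai")
                or os.path.exists(s.alignment_path + ".csi")
            ):
                raise ConfigError(f"sample {s.id!r}: alignment file is not indexed")
    roles = {s.role for s in samples}
    for missing in (HETEROGAMETIC, HOMOGAMETIC) :
        if missing not in roles:
            het_sex = MALE if config.system == "XY" else FEMALE
            sex = het_sex if missing == HETEROGAMETIC else (FEMALE if het_sex == MALE else MALE)
            raise ConfigError(
                f"no {missing} sample in the sheet: system {config.system} requires "
                f"at least one {sex} sample"
            )
    return list(samples)


def assembly_n50(index: GenomeIndex) -> int:
    """N50: largest-first cumulative scaffold length reaching half the total."""
    lengths = sorted((l for _, l in index.scaffolds), reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    return 0
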