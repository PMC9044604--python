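"""Shared fixtures: tiny BAM builders and session-scoped simulated runs."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from sexscan.core import RunConfig
from sexscan.pipeline import run_pipeline
from sexscan.simulate import (
    SimSample,
    SimScenario,
    preset_scenario,
    simulate_all,
)


def write_bam(path, refs: dict[str, int], records: list[dict]) -> str:
    """Write a small coordinate-sorted indexed BAM from record dicts.

    Record keys: name, ref, pos, cigar (default '100M'), mapq (60),
    flag (0), nm (0 or None to omit the tag).
    """
    header = pysam.AlignmentHeader.from_references(
        list(refs.keys()), list(refs.values())
    )
    ref_ids = {n: i for i, n in enumerate(refs)}
    recs = []
    for i, d in enumerate(records):
        a = pysam.AlignedSegment(header)
        a.query_name = d.get("name", f"r{i}")
        a.flag = d.get("flag", 0)
        a.reference_id = ref_ids[d["ref"]]
        a.reference_start = d["pos"]
        a.mapping_quality = d.get("mapq", 60)
        a.cigarstring = d.get("cigar", "100M")
        if d.get("nm", 0) is not None:
            a.set_tag("NM", d.get("nm", 0))
        recs.append(a)
    recs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
        for a in recs:
            bf.write(a)
    pysam.index(str(path))
    return str(path)


def random_records(rng, refs: dict[str, int], n: int, read_len: int = 100):
    """Random positions/CIGARs (matches, deletions, insertions, soft clips)."""
    out = []
    names = list(refs)
    for i in range(n):
        ref = names[rng.integers(len(names))]
        pos = int(rng.integers(0, max(refs[ref] - 2 * read_len, 1)))
        style = rng.integers(4)
        if style == 0:
            cigar = f"{read_len}M"
        elif style == 1:
            d = int(rng.integers(1, 30))
            cigar = f"{read_len // 2}M{d}D{read_len - read_len // 2}M"
        elif style == 2:
            ins = int(rng.integers(1, 10))
            cigar = f"{read_len // 2}M{ins}I{read_len // 2 - ins}M"
        else:
            clip = int(rng.integers(1, 20))
            cigar = f"{clip}S{read_len - clip}M"
        out.append(
            {
                "ref": ref,
                "pos": pos,
                "cigar": cigar,
                "nm": int(rng.poisson(1.0)),
                "mapq": int(60 if rng.random() > 0.05 else 0),
                "flag": int(1024 if rng.random() < 0.05 else 0),
            }
        )
    return out


def tiny_scenario(seed: int = 5) -> SimScenario:
    """A 2 Mb null scenario small enough for repeated full runs."""
    return SimScenario(
        scaffolds=[("c1", 1_200_000), ("c2", 800_000)],
        regions=[],
        samples=[SimSample("F1", "female", 6.0), SimSample("M1", "male", 5.0)],
        seed=seed,
        unit_window=5000,
        report_window=50_000,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny")
    paths = simulate_all(tiny_scenario(), outdir, synteny_mode="identity")
    return paths


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset):
    cfg = RunConfig.from_yaml(tiny_dataset["config"])
    return run_pipeline(cfg, render=False)


@pytest.fixture(scope="session")
def fig1d_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fig1d")
    scenario = preset_scenario("fig1d", seed=11)
    paths = simulate_all(scenario, outdir, synteny_mode="identity")
    return {"scenario": scenario, **paths}


@pytest.fixture(scope="session")
def fig1d_run(fig1d_dataset):
    cfg = RunConfig.from_yaml(fig1d_dataset["config"])
    return run_pipeline(cfg)  # rendered: reporting tests reuse the artifacts


@pytest.fixture(scope="session")
def fig1b_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fig1b")
    scenario = preset_scenario("fig1b", seed=23)
    paths = simulate_all(scenario, outdir)
    return {"scenario": scenario, **paths}


@pytest.fixture(scope="session")
def fig1b_run(fig1b_dataset):
    cfg = RunConfig.from_yaml(fig1b_dataset["config"])
    return run_pipeline(cfg, render=False)
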