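"""Shared fixtures: the preset study design, mapped read sets, and a
random-event planting helper that guarantees observable junctions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from tdnascope.align_core import (
    IndexedReference,
    filter_long_reads,
    group_by_read,
    map_read,
)
from tdnascope.models import (
    Feature,
    Genome,
    IntegrationEvent,
    TDnaConstruct,
    revcomp,
)
from tdnascope.simgen import (
    VECTOR_NAME,
    HostGenomeSpec,
    LongReadSimParams,
    ShortReadSimParams,
    _no_positive_prefix,
    build_host_genome,
    build_sample_genomes,
    build_transgenic_haplotype,
    generate_filler,
    pb29_preset,
    simulate_long_reads,
    simulate_short_reads,
)


@pytest.fixture(scope="session")
def preset():
    return pb29_preset()


@pytest.fixture(scope="session")
def preset_samples(preset):
    """(wildtype haplotypes, transgenic haplotypes, truth records), seed 7."""
    return build_sample_genomes(
        preset.host, preset.construct, preset.events, preset.design, seed=7
    )


@pytest.fixture(scope="session")
def long_index(preset):
    return IndexedReference.from_genome(
        preset.host, vector=preset.construct.sequence, k=13
    )


@pytest.fixture(scope="session")
def preset_long_records(preset, preset_samples, long_index):
    """Error-free 40x long reads from the transgenic sample, mapped.

    Returns (records grouped by read, read sequences, SimulatedReads).
    """
    _, tg_set, _ = preset_samples
    sim = simulate_long_reads(tg_set, LongReadSimParams(seed=8, coverage=40.0))
    kept, _ = filter_long_reads(sim.reads, 500)
    records = []
    for rid, seq, _ in kept:
        records.extend(map_read(long_index, rid, seq))
    seqs = {rid: seq for rid, seq, _ in kept}
    return group_by_read(records), seqs, sim


@pytest.fixture(scope="session")
def full_report():
    """The complete pb29 pipeline run used by the acceptance tests."""
    from tdnascope.report import run_pipeline

    return run_pipeline({"seed": 7})


# ---------------------------------------------------------------------------
# random observable events


def small_construct(rng: np.random.Generator, length: int = 3000) -> TDnaConstruct:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=length).tobytes().decode()
    return TDnaConstruct(
        seq,
        [
            Feature("LB", 1, 25),
            Feature("cassette", 1000, 1999),
            Feature("RB", length - 24, length),
        ],
    )


def _junctions_observable(
    host_seq: str,
    del_start: int,
    del_end: int,
    insert: str,
    construct: TDnaConstruct,
    event: IntegrationEvent,
) -> bool:
    """String-level check that every planted breakpoint is recoverable:
    no alignment can gain score by crossing a junction."""
    window = 50
    if not _no_positive_prefix(
        insert[:window], host_seq[del_start - 1 : del_start - 1 + window]
    ):
        return False
    if not _no_positive_prefix(
        insert[::-1][:window], host_seq[max(0, del_end - window) : del_end][::-1]
    ):
        return False
    # vector-alignment boundaries against fillers (forward-layout check;
    # a reverse unit is the forward case on the reverse-complemented insert)
    if event.orientation == "forward":
        fl, fr = event.filler_left, event.filler_right
    else:
        fl, fr = revcomp(event.filler_right), revcomp(event.filler_left)
    L = construct.length
    if fl and not _no_positive_prefix(
        fl[::-1], construct.sequence[: event.lb_trunc][::-1]
    ):
        return False
    if fr and not _no_positive_prefix(
        fr, construct.sequence[L - event.rb_trunc :]
    ):
        return False
    return True


@dataclass
class PlantedCase:
    host: Genome
    construct: TDnaConstruct
    event: IntegrationEvent
    haplotype: Genome
    truth: Dict


def plant_random_event(seed: int, host_len: int = 40000) -> PlantedCase:
    """One random single-copy integration with observable junctions."""
    rng = np.random.default_rng(seed)
    spec = HostGenomeSpec({"chrA": host_len}, gc=0.38, seed=seed)
    host = build_host_genome(spec)
    construct = small_construct(rng)
    L = construct.length

    for attempt in range(200):
        width = int(rng.integers(0, 41))
        lb = int(rng.integers(0, 46))
        rb = int(rng.integers(0, 46))
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        excise = rng.random() < 0.5
        filler_sides = [rng.random() < 0.4, rng.random() < 0.4]
        fillers = []
        for has in filler_sides:
            if has:
                fillers.append(
                    generate_filler(
                        rng,
                        int(rng.integers(12, 41)),
                        [host["chrA"], construct.sequence],
                    )
                )
            else:
                fillers.append("")
        del_start = int(rng.integers(host_len // 4, host_len // 2))
        event = IntegrationEvent(
            chrom="chrA",
            del_start=del_start,
            del_end=del_start + width - 1,
            copies=[orientation],
            lb_trunc=lb,
            rb_trunc=rb,
            filler_left=fillers[0],
            filler_right=fillers[1],
            deleted_features=frozenset({"cassette"}) if excise else frozenset(),
        )
        try:
            hap, truth = build_transgenic_haplotype(host, construct, event)
        except ValueError:
            continue
        if _junctions_observable(
            host["chrA"], event.del_start, event.del_end,
            truth["insert_seq"], construct, event,
        ):
            return PlantedCase(host, construct, event, hap, truth)
    raise RuntimeError("no observable random event found")


def analyze_planted_case(case: PlantedCase, coverage: float = 30.0, seed: int = 3):
    """Map long reads from a planted haplotype and resolve the insertion."""
    from tdnascope.insert_annotator import characterize_insert
    from tdnascope.longread_resolver import reconstruct_insert
    from tdnascope.report import calls_from_long_reads

    index = IndexedReference.from_genome(
        case.host, vector=case.construct.sequence, k=13
    )
    sim = simulate_long_reads(
        [(case.haplotype, 1.0)],
        LongReadSimParams(
            seed=seed, coverage=coverage, median_length=8000.0, sigma_log=0.3
        ),
    )
    records = []
    for rid, seq, _ in sim.reads:
        records.extend(map_read(index, rid, seq))
    grouped = group_by_read(records)
    seqs = {rid: seq for rid, seq, _ in sim.reads}
    calls = calls_from_long_reads(grouped, case.construct.length)
    recon = None
    char = None
    if calls:
        recon = reconstruct_insert(grouped, seqs, calls[0])
    if recon is not None:
        char = characterize_insert(recon.consensus, case.construct, index)
    return calls, recon, char
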