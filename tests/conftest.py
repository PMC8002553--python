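"""Shared fixtures: small references, vectors and preset pipeline runs."""

from __future__ import annotations

import pytest

from vectorint.pipeline import characterize, verify_against_truth
from vectorint.simulate import (
    build_vector,
    generate_reference,
    simulate_line,
)


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(2, [5000, 5000], gc=0.5, seed=42)


@pytest.fixture(scope="session")
def small_vector(small_reference):
    return build_vector(
        small_reference,
        3000,
        feature_plan=[("marker", 500, 1309, "+"), ("reporter", 1400, 2200, "+")],
        host_segments=[("chr01", 3000, 4200, 1700)],
        seed=7,
    )


def run_preset(preset: str, seed: int = 1, depth: float = 100.0,
               error_rate: float = 0.0):
    """Simulate one preset and run the full in-memory pipeline on it."""
    sim = simulate_line(preset, seed=seed, depth=depth, error_rate=error_rate)
    report = characterize(
        reference=sim.reference.as_dict(),
        vector_seq=sim.vector.sequence,
        vector_features=list(sim.vector.features),
        pairs=sim.reads,
        contigs=[sim.contig] if sim.contig is not None else [],
        gff_rows=gff_rows_from_sim(sim),
        line=preset,
    )
    card = (verify_against_truth(report, sim.truth.to_json_dict())
            if sim.truth is not None else None)
    return sim, report, card


def gff_rows_from_sim(sim) -> list[dict]:
    rows = []
    for seqid, _src, ftype, start, end, strand, attrs in sim.gff:
        rows.append(
            {
                "seqid": seqid,
                "type": ftype,
                "start": start,
                "end": end,
                "strand": strand,
                "attrs": dict(kv.split("=", 1) for kv in attrs.split(";")),
            }
        )
    return rows


@pytest.fixture(scope="session")
def preset_runner():
    return run_preset


@pytest.fixture(scope="session")
def t3_run():
    """One full T3 pipeline run shared across tests (most-used preset)."""
    return run_preset("T3", seed=1)


@pytest.fixture(scope="session")
def nt_run():
    return run_preset("NT", seed=1)
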