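"""Shared fixtures.

Expensive synthetic bundles (the planted demo genome, the 30x read
simulation and full calling cascade, the probe-track recovery run) are
session-scoped so the acceptance tests and unit tests share one
computation.
"""

from __future__ import annotations

import dataclasses

import pytest

from shattercall import datasets
from shattercall.cna_calling import call_cnas, segment_probe_track, subtract_baseline
from shattercall.sv_calling import CallerConfig, call_rearrangements
from shattercall.synthetic_data import (
    ReadSimParams,
    generate_reference,
    plant_rearrangements,
    rescale_cna_segments,
    rescale_events,
    simulate_probe_track,
    simulate_read_pairs,
)


@pytest.fixture(scope="session")
def demo_events():
    return datasets.demo_rearrangements()


@pytest.fixture(scope="session")
def demo_bundle(demo_events):
    """Rescaled demo events planted in a seeded synthetic genome."""
    scaled, rmap = rescale_events(demo_events)
    ref = generate_reference(rmap.chrom_lengths, gc_fraction=0.41, seed=1)
    derivative = plant_rearrangements(ref, scaled, rescale_map=rmap)
    return {"scaled_events": scaled, "rmap": rmap, "derivative": derivative}


@pytest.fixture(scope="session")
def sv_run(demo_bundle):
    """Full 30x simulation + calling cascade on the demo genome."""
    derivative = demo_bundle["derivative"]
    params = ReadSimParams(seed=1)
    sample = simulate_read_pairs(derivative, params)
    parental = [
        simulate_read_pairs(derivative.reference, dataclasses.replace(params, seed=s))
        for s in (2, 3)
    ]
    result = call_rearrangements(sample, parental, derivative.reference, CallerConfig())
    return {
        "derivative": derivative,
        "sample_pairs": sample,
        "parental_pairs": parental,
        "result": result,
    }


@pytest.fixture(scope="session")
def cna_run():
    """Rescaled demo copy-number segments recovered from a noisy track."""
    truth, rmap = rescale_cna_segments(datasets.demo_cna_segments())
    sample = simulate_probe_track(rmap.chrom_lengths, truth, 1_000, 0.3, seed=11)
    baseline = simulate_probe_track(rmap.chrom_lengths, [], 1_000, 0.3, seed=12)
    differential = subtract_baseline(sample, baseline)
    segments = segment_probe_track(differential)
    calls = call_cnas(segments)
    return {
        "truth": truth,
        "rmap": rmap,
        "sample": sample,
        "baseline": baseline,
        "differential": differential,
        "segments": segments,
        "calls": calls,
    }
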