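"""Shared fixtures: small hand-built tables and one full-scale simulation.

The full-scale dataset (10 locations x 2 jars, 9 technical replicates of
20,000 reads each, 12 controls) is expensive, so it is simulated once per
session and shared by the end-to-end tests.
"""

from __future__ import annotations

import logging

import pytest

from haplocheck.pipeline import run_arm, simulate_dataset
from haplocheck.simulate import SimulationParams
from haplocheck.types import (
    Feature,
    FeatureSet,
    ReferenceRecord,
    ReferenceSet,
    ReplicateCountTable,
    RunConfig,
    Sample,
    SampleDesign,
    build_design,
)

logging.getLogger("haplocheck").setLevel(logging.ERROR)


@pytest.fixture
def toy_design() -> SampleDesign:
    samples = [
        Sample("s1", "L01", "A"),
        Sample("s2", "L01", "B"),
    ]
    return SampleDesign(samples, replicates_per_sample=9,
                        control_combos=["c1", "c2", "c3"])


@pytest.fixture
def toy_refs() -> ReferenceSet:
    return ReferenceSet([
        ReferenceRecord("r1", "spX", "X-H1", "ACGTACGTACGTACGTACGT"),
        ReferenceRecord("r2", "spX", "X-H2", "ACGTACGTACGAACGTACGT"),
        ReferenceRecord("r3", "spY", "Y-H1", "TGCATGCATGCATGCATGCA"),
    ])


def make_features(design: SampleDesign, spec: dict[str, dict[str, int]]) -> FeatureSet:
    """Features from {sequence: {replicate: count}}, ids in given order."""
    feats = [
        Feature(f"F{i + 1:03d}", seq, dict(counts), members=[seq])
        for i, (seq, counts) in enumerate(spec.items())
    ]
    return FeatureSet(feats, design)


def make_table(design: SampleDesign, entries: dict[str, dict[str, int]]) -> ReplicateCountTable:
    return ReplicateCountTable(design, entries)


@pytest.fixture(scope="session")
def full_dataset():
    """Study-design-scale simulation: the shared end-to-end ground truth."""
    return simulate_dataset(SimulationParams(), seed=1)


@pytest.fixture(scope="session")
def denoiser_arm(full_dataset):
    """Denoiser arm with chimera removal on the full-scale dataset."""
    cfg = RunConfig(stage="denoiser", chimera_removal=True, seed=1)
    return run_arm(full_dataset, cfg)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """Reduced problem size for pipeline-level tests."""
    return SimulationParams(n_locations=4, depth_per_replicate=1000)
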