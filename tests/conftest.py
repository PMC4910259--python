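"""Shared synthetic worlds for the test suite.

``toy_world`` is the default-scale study (1 x 2 Mb chromosome, 200
elements, 50 samples); building it once per session keeps the statistical
tests affordable.  ``mini_world`` is a down-scaled variant for file-format
and CLI round-trips.
"""

from __future__ import annotations

from dataclasses import replace
from typing import NamedTuple

import pytest

import fmlbias as F


class World(NamedTuple):
    spec: F.SyntheticSpec
    genome: F.ReferenceGenome
    catalog: F.ElementCatalog
    store: F.InMemoryScoreStore
    hotspots: dict
    scorer: F.ElementScorer


def _build(spec: F.SyntheticSpec) -> World:
    genome = F.generate_genome(spec)
    catalog = F.build_toy_catalog(spec, genome)
    store, hotspots = F.generate_scores(spec, genome, catalog)
    return World(spec, genome, catalog, store, hotspots, F.ElementScorer(store, genome))


@pytest.fixture(scope="session")
def toy_world() -> World:
    return _build(F.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def driver_spec(toy_world) -> F.SyntheticSpec:
    # same genome/catalog/scores as toy_world; only cohort drawing differs
    return replace(toy_world.spec, driver_elements=("SYNG0005:cds",))


@pytest.fixture(scope="session")
def mini_world() -> World:
    spec = F.SyntheticSpec(
        chrom_length=200_000, n_protein_coding=4, n_lincrna=1,
        n_samples=10, mutations_per_sample=20.0, seed=11,
    )
    return _build(spec)
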