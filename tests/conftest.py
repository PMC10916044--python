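"""Shared fixtures: seeded toy genomes and designed manifests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from epickit import GenomeVariantSet, ManifestTable, generate_toy_genome
from epickit.simulate import DESIGN_COMBOS, cpg_positions, design_manifest, design_probe


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(length=12_000, cpg_density=0.05, seed=2)


@pytest.fixture(scope="session")
def cpg_targets(toy_genome):
    return cpg_positions(toy_genome)


@pytest.fixture(scope="session")
def designed_manifest(toy_genome) -> ManifestTable:
    return design_manifest(toy_genome, 32, seed=4)


@pytest.fixture(scope="session")
def variants(toy_genome) -> GenomeVariantSet:
    return GenomeVariantSet(toy_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def one_probe_per_combo(toy_genome, cpg_targets):
    """One designed probe for each of the 8 (TB x CO x type) combinations."""
    out = {}
    for i, combo in enumerate(DESIGN_COMBOS):
        chrom, pos = cpg_targets[10 + i]
        out[combo] = design_probe(toy_genome, chrom, pos, *combo)
    return out
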