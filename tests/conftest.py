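"""Shared fixtures: one small simulated population reused across modules."""

import numpy as np
import pytest

from aquagsel import impute, qc, simdata


@pytest.fixture(scope="session")
def small_preset():
    return simdata.salmon_like(
        n_snps=2000,
        n_chromosomes=10,
        n_parents=40,
        n_families=50,
        n_offspring=500,
        h2=0.4,
    )


@pytest.fixture(scope="session")
def small_sim(small_preset):
    """One 40-parent / 50-family / 500-offspring population, 2k SNPs."""
    return simdata.simulate_population(small_preset, seed=7)


@pytest.fixture(scope="session")
def qc_population(small_sim):
    """SNP-filtered genotypes with the matching map."""
    _, geno = qc.filter_snps(small_sim.genotypes, small_sim.marker_map, small_sim.pedigree)
    return geno, small_sim.marker_map.subset(geno.snps)


@pytest.fixture(scope="session")
def phased_parents(small_sim, qc_population):
    """Heuristically phased parents of the small population."""
    geno, mmap = qc_population
    parents = [p for p in small_sim.parent_ids if p in set(geno.ids)]
    return impute.phase_parents(geno.subset(ids=parents), mmap, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
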