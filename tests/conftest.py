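"""Shared fixtures: tiny programmatically generated genomes and populations."""

from __future__ import annotations

import numpy as np
import pytest

from pagesim.breeding import Population
from pagesim.founders import FounderHaplotypes
from pagesim.genome import DemographySchedule, GenomeMap
from pagesim.trait import TraitArchitecture


@pytest.fixture(scope="session")
def small_genome() -> GenomeMap:
    return GenomeMap(n_chromosomes=2, chrom_length_cm=100.0, chrom_length_bp=1_000_000, mu=2.5e-8)


@pytest.fixture(scope="session")
def default_schedule() -> DemographySchedule:
    return DemographySchedule()


def make_founders(genome: GenomeMap, n_hap: int = 20, sites_per_chrom: int = 50, seed: int = 0) -> FounderHaplotypes:
    """Random segregating founder haplotypes (not coalescent; for unit tests)."""
    rng = np.random.default_rng(seed)
    haps, pos = [], []
    for c in range(genome.n_chromosomes):
        while True:
            h = (rng.random((n_hap, sites_per_chrom)) < rng.uniform(0.1, 0.9, sites_per_chrom)).astype(np.uint8)
            counts = h.sum(axis=0)
            if np.all((counts > 0) & (counts < n_hap)):
                break
        p = np.sort(rng.choice(np.arange(1, genome.chrom_length_bp + 1), size=sites_per_chrom, replace=False))
        haps.append(h)
        pos.append(p.astype(np.int64))
    return FounderHaplotypes(haplotypes=haps, positions_bp=pos, genome=genome)


@pytest.fixture()
def small_founders(small_genome) -> FounderHaplotypes:
    return make_founders(small_genome)


def make_arch(genome: GenomeMap, founders: FounderHaplotypes, n_qtn: int = 20, seed: int = 1) -> TraitArchitecture:
    from pagesim.trait import build_architecture

    return build_architecture(founders, n_qtn, seed=seed)


@pytest.fixture()
def small_arch(small_genome, small_founders) -> TraitArchitecture:
    return make_arch(small_genome, small_founders)


def make_population(
    arch: TraitArchitecture,
    n: int = 20,
    generation: int = 0,
    seed: int = 2,
    genomes: np.ndarray | None = None,
) -> Population:
    rng = np.random.default_rng(seed)
    if genomes is None:
        genomes = rng.integers(0, 2, size=(n, 2, arch.n_qtn), dtype=np.uint8)
    sex = np.zeros(n, dtype=np.uint8)
    sex[n // 2 :] = 1
    pop = Population(
        generation=generation,
        ids=np.arange(1, n + 1, dtype=np.int64),
        sex=sex,
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        genomes=genomes,
        tbv=np.zeros(n),
    )
    pop.tbv = arch.tbv_of(pop.genomes)
    return pop


@pytest.fixture()
def small_population(small_arch) -> Population:
    return make_population(small_arch)
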