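"""Gene-drop breeding simulation: selection, mating, meiosis, pedigree.

Each discrete, non-overlapping generation comprises 1000 individuals
(500 males, 500 females) by default.  The top 25 males and all 500
females by TBV are selected as parents; every dam produces exactly two
offspring by the same sire, and every sire receives an equal number of
dams, so all selected sires contribute equally to the next generation.

Meiosis follows the Haldane (no-interference) model: the number of
crossovers per chromosome is Poisson with mean equal to the genetic
length in Morgans, crossover positions are uniform on the genetic map,
and the starting parental strand is chosen with probability 1/2.
Genomes are tracked at QTN loci only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .trait import TraitArchitecture

__all__ = [
    "Population",
    "MatingPlan",
    "select_parents",
    "make_mating_plan",
    "meiosis",
    "advance_generation",
    "run_historical",
]

MALE, FEMALE = 0, 1


@dataclass
class Population:
    """One generation of individuals, stored as flat arrays.

    ``genomes`` has shape ``(n, 2, n_qtn)`` with uint8 alleles in {0, 1};
    axis 1 is the two gametic haplotypes.  ``sire``/``dam`` hold parent
    ids, 0 meaning founder/unknown.
    """

    generation: int
    ids: np.ndarray
    sex: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    genomes: np.ndarray
    tbv: np.ndarray
    edits: dict[int, np.ndarray] = field(default_factory=dict)  # individual id -> edited QTN ids

    def __post_init__(self) -> None:
        n = self.ids.size
        if len(np.unique(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        if not (self.sex.size == self.sire.size == self.dam.size == self.tbv.size == n):
            raise ValueError("inconsistent per-individual array lengths")
        if self.genomes.shape[0] != n or self.genomes.shape[1] != 2:
            raise ValueError("genomes must have shape (n, 2, n_qtn)")

    @property
    def n_individuals(self) -> int:
        return int(self.ids.size)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def allele1_frequency(self) -> np.ndarray:
        """Frequency of allele 1 at every locus among the 2n gametes."""
        return self.genomes.sum(axis=(0, 1), dtype=np.int64) / (2 * self.n_individuals)

    def copy(self) -> "Population":
        return Population(
            generation=self.generation,
            ids=self.ids.copy(),
            sex=self.sex.copy(),
            sire=self.sire.copy(),
            dam=self.dam.copy(),
            genomes=self.genomes.copy(),
            tbv=self.tbv.copy(),
            edits={k: v.copy() for k, v in self.edits.items()},
        )

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": np.where(self.sex == MALE, "M", "F"),
                "generation": self.generation,
                "tbv": self.tbv,
            }
        )


def _rank_by_tbv(pop: Population, candidates: np.ndarray) -> np.ndarray:
    """Candidate positions ordered by TBV descending, ties by ascending id."""
    order = np.lexsort((pop.ids[candidates], -pop.tbv[candidates]))
    return candidates[order]


def select_parents(pop: Population, n_sires: int = 25, n_dams: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Truncation selection on TBV within each sex.

    Returns positional indices of the selected sires and dams, each
    ordered by TBV descending (ties by ascending id).  With the default
    500-of-500 females, dam "selection" retains every female.
    """
    males, females = pop.males, pop.females
    if males.size < n_sires:
        raise ValueError(f"need {n_sires} male candidates, have {males.size}")
    if females.size < n_dams:
        raise ValueError(f"need {n_dams} female candidates, have {females.size}")
    return _rank_by_tbv(pop, males)[:n_sires], _rank_by_tbv(pop, females)[:n_dams]


@dataclass
class MatingPlan:
    """Offspring-level mating assignment.

    ``sire_of`` / ``dam_of`` give, for each of the ``n_offspring`` future
    individuals, the positional index of its parents in the current
    population.  Both offspring of a dam share the same sire.
    """

    sire_of: np.ndarray
    dam_of: np.ndarray

    @property
    def n_offspring(self) -> int:
        return int(self.sire_of.size)

    def triples(self, pop: Population) -> pd.DataFrame:
        """(sire_id, dam_id, n_offspring) summary of the plan."""
        df = pd.DataFrame({"sire_id": pop.ids[self.sire_of], "dam_id": pop.ids[self.dam_of]})
        return df.value_counts().rename("n_offspring").reset_index()


def make_mating_plan(
    sires: np.ndarray,
    dams: np.ndarray,
    n_offspring: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MatingPlan:
    """Equal-contribution mating design.

    Each dam produces exactly ``n_offspring / n_dams`` offspring (2 by
    default) all by the same sire; each sire serves ``n_dams / n_sires``
    dams chosen uniformly at random.  Non-integral quotas are an error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sires, n_dams = sires.size, dams.size
    if n_offspring % n_dams:
        raise ValueError(f"{n_offspring} offspring not divisible by {n_dams} dams")
    if n_offspring % n_sires or n_dams % n_sires:
        raise ValueError(f"{n_offspring} offspring / {n_dams} dams not divisible by {n_sires} sires")
    per_dam = n_offspring // n_dams
    dams_per_sire = n_dams // n_sires
    shuffled = rng.permutation(dams)
    dam_of = np.repeat(shuffled, per_dam)
    sire_of = np.repeat(sires, dams_per_sire * per_dam)
    return MatingPlan(sire_of=sire_of, dam_of=dam_of)


def _drop_gametes(
    parent_haps: np.ndarray,
    gpos_m: np.ndarray,
    chrom_length_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Batched meiosis for one chromosome.

    ``parent_haps`` is ``(n_gametes, 2, L)``: the two parental strands for
    each requested gamete.  Crossover counts are Poisson(chromosome length
    in Morgans), positions uniform on the genetic map, starting strand
    fair.  Returns ``(n_gametes, L)`` gametes.
    """
    n, _, L = parent_haps.shape
    n_co = rng.poisson(chrom_length_m, size=n)
    start = rng.integers(0, 2, size=n)
    kmax = int(n_co.max(initial=0))
    if kmax == 0:
        return parent_haps[np.arange(n), start]
    co = rng.uniform(0.0, chrom_length_m, size=(n, kmax))
    co[np.arange(kmax)[None, :] >= n_co[:, None]] = np.inf  # pad unused draws
    # strand at a locus flips once per crossover to its left
    n_left = (co[:, :, None] < gpos_m[None, None, :]).sum(axis=1)
    strand = (start[:, None] + n_left) & 1
    return parent_haps[np.arange(n)[:, None], strand, np.arange(L)[None, :]]


def meiosis(
    parent_genome: np.ndarray,
    genome: GenomeMap,
    arch: TraitArchitecture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete ``(n_qtn,)`` from a parent genome ``(2, n_qtn)``."""
    gamete = np.empty(arch.n_qtn, dtype=np.uint8)
    gpos = arch.gpos_m
    for c in range(genome.n_chromosomes):
        sl = arch.chrom_slice(c)
        gamete[sl] = _drop_gametes(
            parent_genome[None, :, sl], gpos[sl], genome.chrom_length_morgans, rng
        )[0]
    return gamete


def advance_generation(
    pop: Population,
    plan: MatingPlan,
    genome: GenomeMap,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> Population:
    """Create the next generation from a mating plan.

    Every offspring receives one paternal and one maternal gamete per
    chromosome (independent meioses); sexes are an exactly half/half
    label vector under a random permutation; pedigree links and TBVs are
    recorded.
    """
    n_off = plan.n_offspring
    if n_off % 2:
        raise ValueError("offspring count must be even for the 50/50 sex split")
    genomes = np.empty((n_off, 2, arch.n_qtn), dtype=np.uint8)
    gpos = arch.gpos_m
    for c in range(genome.n_chromosomes):
        sl = arch.chrom_slice(c)
        for axis, parent_of in ((0, plan.sire_of), (1, plan.dam_of)):
            parent_haps = pop.genomes[parent_of][:, :, sl]
            genomes[:, axis, sl] = _drop_gametes(
                parent_haps, gpos[sl], genome.chrom_length_morgans, rng
            )
    sex = np.zeros(n_off, dtype=np.uint8)
    sex[n_off // 2 :] = FEMALE
    sex = sex[rng.permutation(n_off)]
    if id_start is None:
        id_start = int(pop.ids.max()) + 1
    ids = np.arange(id_start, id_start + n_off, dtype=np.int64)
    return Population(
        generation=pop.generation + 1,
        ids=ids,
        sex=sex,
        sire=pop.ids[plan.sire_of],
        dam=pop.ids[plan.dam_of],
        genomes=genomes,
        tbv=arch.tbv_of(genomes),
    )


def run_historical(
    base_pop: Population,
    genome: GenomeMap,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    n_generations: int = 20,
    n_sires: int = 25,
    n_dams: int = 500,
    select: bool = True,
    recorder=None,
) -> Population:
    """Run the historical breeding phase (generation -20 up to 0).

    Repeated select -> mate -> advance with no editing.  ``select=False``
    replaces truncation selection with a random draw of parents (used for
    drift-only checks).  ``recorder``, when given, is called with each
    population (including the base one) to accumulate metrics/pedigree.
    """
    pop = base_pop
    if recorder is not None:
        recorder(pop, None)
    for _ in range(n_generations):
        if select:
            sires, dams = select_parents(pop, n_sires, n_dams)
        else:
            sires = rng.choice(pop.males, size=n_sires, replace=False)
            dams = rng.choice(pop.females, size=n_dams, replace=False)
        plan = make_mating_plan(sires, dams, pop.n_individuals, rng)
        pop = advance_generation(pop, plan, genome, arch, rng)
        if recorder is not None:
            recorder(pop, plan)
    return pop
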