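"""Founder haplotypes: coalescent simulation, text import/export, base population.

Founder genetic diversity is produced by a coalescent simulation under the
piecewise-linear Ne history of :class:`~pagesim.genome.DemographySchedule`,
using msprime's sequentially-Markov (SMC') approximation for speed on
chromosome-scale sequences.  Alternatively, haplotypes can be imported from
a plain-text matrix (one haplotype per row, ``0``/``1`` characters) with a
companion file of physical positions.

The base population of the breeding program is instantiated by drawing,
independently per chromosome and with replacement, two founder haplotypes
per individual, then projecting genomes down to the QTN loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import msprime
import numpy as np

from .genome import DemographySchedule, GenomeMap

if TYPE_CHECKING:  # pragma: no cover
    from .breeding import Population
    from .trait import TraitArchitecture

logger = logging.getLogger(__name__)

__all__ = [
    "FounderHaplotypes",
    "simulate_founder_haplotypes",
    "load_founder_haplotypes",
    "save_founder_haplotypes",
    "build_base_population",
]


@dataclass
class FounderHaplotypes:
    """Per-chromosome founder haplotype matrices.

    Attributes
    ----------
    haplotypes
        One ``(n_haplotypes, S_c)`` uint8 matrix per chromosome, entries in
        {0, 1}, every column segregating.
    positions_bp
        One strictly increasing int64 array of 1-based physical positions
        per chromosome, aligned with the matrix columns.
    genome
        The genome map the haplotypes were generated under.
    """

    haplotypes: list[np.ndarray]
    positions_bp: list[np.ndarray]
    genome: GenomeMap

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.positions_bp):
            raise ValueError("haplotypes and positions_bp must have one entry per chromosome")
        n_hap = {h.shape[0] for h in self.haplotypes}
        if len(n_hap) > 1:
            raise ValueError("haplotype count must be identical across chromosomes")
        for c, (h, p) in enumerate(zip(self.haplotypes, self.positions_bp)):
            if h.shape[1] != p.shape[0]:
                raise ValueError(f"chromosome {c}: {h.shape[1]} columns but {p.shape[0]} positions")
            if p.size and (np.any(np.diff(p) <= 0)):
                raise ValueError(f"chromosome {c}: positions must be strictly increasing")
            if p.size and (p[0] < 1 or p[-1] > self.genome.chrom_length_bp):
                raise ValueError(f"chromosome {c}: positions outside [1, chrom_length_bp]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes[0].shape[0])

    @property
    def sites_per_chromosome(self) -> list[int]:
        return [int(h.shape[1]) for h in self.haplotypes]

    @property
    def total_segregating_sites(self) -> int:
        return int(sum(self.sites_per_chromosome))


def _msprime_demography(schedule: DemographySchedule, n_epochs: int = 160) -> msprime.Demography:
    """Stepwise msprime demography approximating the piecewise-linear schedule.

    Epoch boundaries are geometrically spaced between 1 generation ago and
    the oldest anchor; each epoch takes the schedule's Ne at its midpoint.
    """
    oldest = float(schedule.times[-1])
    if oldest <= 0:  # single-anchor (constant) history
        bounds = np.array([0.0])
    else:
        bounds = np.unique(np.concatenate([[0.0], np.geomspace(1.0, oldest, n_epochs)]))
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=float(schedule.ne_at(0.0)))
    for i in range(1, len(bounds)):
        mid = 0.5 * (bounds[i - 1] + bounds[i])
        dem.add_population_parameters_change(time=bounds[i - 1], initial_size=float(schedule.ne_at(mid)))
    if oldest > 0:
        dem.add_population_parameters_change(time=oldest, initial_size=float(schedule.sizes[-1]))
    return dem


def simulate_founder_haplotypes(
    genome: GenomeMap,
    schedule: DemographySchedule,
    n_haplotypes: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    model: str | None = "smc_prime",
) -> FounderHaplotypes:
    """Simulate founder haplotypes under the demographic schedule.

    One independent coalescent simulation per chromosome, with uniform
    recombination at ``genome.recomb_per_bp`` and biallelic mutations at
    rate ``genome.mu``.  ``model="smc_prime"`` (default) uses the
    sequentially-Markov approximation; ``model=None`` runs the exact
    Hudson coalescent (slower at chromosome scale).

    Parameters
    ----------
    n_haplotypes
        Number of haplotypes sampled per chromosome; must be even (they
        are simulated as ``n_haplotypes / 2`` diploids).
    seed
        Integer seed or a :class:`numpy.random.SeedSequence`; per-chromosome
        msprime seeds are derived from it.
    """
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 2")
    if genome.mu < 0 or genome.recomb_per_bp < 0:
        raise ValueError("rates must be non-negative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chrom_seeds = [int(c.generate_state(1, dtype=np.uint64)[0] % (2**31 - 2)) + 1 for c in ss.spawn(2 * genome.n_chromosomes)]

    sim_model = [msprime.SmcPrimeApproxCoalescent()] if model == "smc_prime" else None
    demography = _msprime_demography(schedule)
    haps: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    for c in range(genome.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_haplotypes // 2,
            ploidy=2,
            sequence_length=genome.chrom_length_bp,
            recombination_rate=genome.recomb_per_bp,
            demography=demography,
            random_seed=chrom_seeds[2 * c],
            model=sim_model,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=genome.mu,
            random_seed=chrom_seeds[2 * c + 1],
            model=msprime.BinaryMutationModel(),
        )
        g = mts.genotype_matrix().astype(np.uint8)  # (sites, haplotypes)
        p = np.floor(mts.sites_position).astype(np.int64) + 1  # 1-based
        # keep one site per integer position, segregating columns only
        keep = np.ones(p.size, dtype=bool)
        if p.size > 1:
            keep[1:] = np.diff(p) > 0
        counts = g.sum(axis=1)
        keep &= (counts > 0) & (counts < n_haplotypes)
        haps.append(np.ascontiguousarray(g[keep].T))
        pos.append(p[keep])
        logger.debug("chromosome %d: %d segregating sites", c, int(keep.sum()))
    return FounderHaplotypes(haplotypes=haps, positions_bp=pos, genome=genome)


def load_founder_haplotypes(
    haplotype_files: Sequence[str | Path],
    position_files: Sequence[str | Path],
    genome: GenomeMap | None = None,
) -> FounderHaplotypes:
    """Parse per-chromosome text haplotypes (rows of 0/1) and positions.

    Monomorphic columns are dropped (count logged).  Malformed input —
    ragged rows, non-binary characters, a position/column count mismatch
    or non-increasing positions — raises ``ValueError`` naming the file
    and line.
    """
    if len(haplotype_files) != len(position_files):
        raise ValueError("need one position file per haplotype file")
    haps: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    n_dropped = 0
    for hap_path, pos_path in zip(haplotype_files, position_files):
        hap_path, pos_path = Path(hap_path), Path(pos_path)
        rows: list[np.ndarray] = []
        width: int | None = None
        with open(hap_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    continue
                if set(s) - {"0", "1"}:
                    raise ValueError(f"{hap_path}:{lineno}: non-binary character in haplotype row")
                if width is None:
                    width = len(s)
                elif len(s) != width:
                    raise ValueError(f"{hap_path}:{lineno}: row of length {len(s)}, expected {width}")
                rows.append(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))
        if not rows:
            raise ValueError(f"{hap_path}: no haplotype rows")
        matrix = np.vstack(rows)
        positions = []
        with open(pos_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    continue
                try:
                    positions.append(int(s))
                except ValueError:
                    raise ValueError(f"{pos_path}:{lineno}: not an integer position") from None
        p = np.asarray(positions, dtype=np.int64)
        if p.size != matrix.shape[1]:
            raise ValueError(f"{pos_path}: {p.size} positions but {matrix.shape[1]} haplotype columns in {hap_path}")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError(f"{pos_path}: positions must be strictly increasing")
        counts = matrix.sum(axis=0)
        seg = (counts > 0) & (counts < matrix.shape[0])
        n_dropped += int((~seg).sum())
        haps.append(np.ascontiguousarray(matrix[:, seg]))
        pos.append(p[seg])
    if n_dropped:
        logger.info("dropped %d monomorphic columns on import", n_dropped)
    if genome is None:
        max_pos = max((int(p[-1]) if p.size else 1) for p in pos)
        genome = GenomeMap(n_chromosomes=len(haps), chrom_length_bp=max(max_pos, 1))
    return FounderHaplotypes(haplotypes=haps, positions_bp=pos, genome=genome)


def save_founder_haplotypes(founders: FounderHaplotypes, out_dir: str | Path, prefix: str = "chr") -> list[tuple[Path, Path]]:
    """Export founder haplotypes in the same text dialect that is imported."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for c in range(founders.n_chromosomes):
        hap_path = out_dir / f"{prefix}{c + 1}.hap.txt"
        pos_path = out_dir / f"{prefix}{c + 1}.pos.txt"
        with open(hap_path, "w") as fh:
            for row in founders.haplotypes[c]:
                fh.write("".join("1" if a else "0" for a in row) + "\n")
        np.savetxt(pos_path, founders.positions_bp[c], fmt="%d")
        files.append((hap_path, pos_path))
    return files


def project_to_qtn(founders: FounderHaplotypes, qtn_site_index: Sequence[np.ndarray]) -> np.ndarray:
    """Restrict founder haplotypes to the QTN columns, concatenated genome-wide.

    Returns a ``(n_haplotypes, n_qtn)`` uint8 matrix ordered chromosome by
    chromosome.
    """
    blocks = [founders.haplotypes[c][:, idx] for c, idx in enumerate(qtn_site_index)]
    return np.ascontiguousarray(np.concatenate(blocks, axis=1))


def build_base_population(
    founders: FounderHaplotypes,
    arch: "TraitArchitecture",
    n_individuals: int = 1000,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    generation: int = -20,
    id_start: int = 1,
) -> "Population":
    """Instantiate the base population from the founder haplotype pool.

    Each individual draws, independently per chromosome and with
    replacement, two haplotypes from the founder pool; genomes are stored
    at QTN loci only.  Sexes are assigned as exactly half male, half
    female; parents are unknown (recorded as 0).
    """
    from .breeding import Population  # deferred to avoid an import cycle

    if n_individuals < 1 or n_individuals % 2:
        raise ValueError("n_individuals must be even and >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qtn_haps = project_to_qtn(founders, arch.qtn_site_index)
    n_hap = founders.n_haplotypes
    genomes = np.empty((n_individuals, 2, arch.n_qtn), dtype=np.uint8)
    for c in range(founders.n_chromosomes):
        sl = arch.chrom_slice(c)
        draw = rng.integers(0, n_hap, size=(n_individuals, 2))
        genomes[:, :, sl] = qtn_haps[draw][:, :, sl]
    sex = np.zeros(n_individuals, dtype=np.uint8)
    sex[n_individuals // 2 :] = 1
    ids = np.arange(id_start, id_start + n_individuals, dtype=np.int64)
    pop = Population(
        generation=generation,
        ids=ids,
        sex=sex,
        sire=np.zeros(n_individuals, dtype=np.int64),
        dam=np.zeros(n_individuals, dtype=np.int64),
        genomes=genomes,
        tbv=np.zeros(n_individuals, dtype=float),
    )
    pop.tbv = arch.tbv_of(genomes)
    return pop
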