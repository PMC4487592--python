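"""Additive trait architecture: QTN, allele-substitution effects, TBV.

The quantitative trait is controlled by ``n_qtn`` biallelic QTN sampled
uniformly (without replacement, equal numbers per chromosome) from the
segregating sites of the founder haplotypes.  Allele-substitution effects
``alpha_i`` are drawn i.i.d. from N(0, (1/sqrt(n_qtn))^2); the favourable
allele at a QTN is allele 1 when ``alpha_i > 0`` and allele 0 otherwise.

True breeding values use the allele-1 dosage coding throughout:

    TBV = sum_i alpha_i * d_i,   d_i = number of copies of allele 1 in {0,1,2}.

Relabelling which allele is "1" at a locus while flipping the sign of
``alpha`` shifts every TBV by the same constant and therefore leaves all
contrasts (selection decisions, responses) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FounderHaplotypes
from .genome import GenomeMap

__all__ = [
    "TraitArchitecture",
    "sample_qtn",
    "sample_effects",
    "compute_tbv",
    "freeze_editability",
    "build_architecture",
]


def sample_qtn(
    founders: FounderHaplotypes,
    n_qtn: int,
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Sample QTN site indices, an equal number per chromosome.

    Returns one sorted array of column indices into the founder haplotype
    matrix per chromosome.
    """
    n_chrom = founders.n_chromosomes
    if n_qtn < 1 or n_qtn % n_chrom:
        raise ValueError(f"n_qtn must be a positive multiple of {n_chrom} chromosomes")
    per_chrom = n_qtn // n_chrom
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c, n_sites in enumerate(founders.sites_per_chromosome):
        if n_sites < per_chrom:
            raise ValueError(
                f"chromosome {c}: {n_sites} segregating sites, need {per_chrom} for QTN sampling"
            )
        out.append(np.sort(rng.choice(n_sites, size=per_chrom, replace=False)))
    return out


def sample_effects(n_qtn: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw allele-substitution effects alpha_i ~ N(0, (1/sqrt(n_qtn))^2).

    Exact zeros (a measure-zero event) are re-drawn so that every QTN has
    a well-defined favourable allele.
    """
    if n_qtn < 1:
        raise ValueError("n_qtn must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = 1.0 / np.sqrt(n_qtn)
    alpha = rng.normal(0.0, sd, size=n_qtn)
    while np.any(alpha == 0.0):
        zero = alpha == 0.0
        alpha[zero] = rng.normal(0.0, sd, size=int(zero.sum()))
    return alpha


@dataclass
class TraitArchitecture:
    """QTN layout, effects and the generation-0 editability mask.

    ``qtn_site_index`` indexes columns of the founder haplotype matrices;
    ``chrom``, ``pos_bp``, ``gpos_m`` and ``alpha`` are flat genome-wide
    arrays ordered chromosome by chromosome.  ``editable`` is None until
    frozen at generation 0 (see :func:`freeze_editability`).
    """

    genome: GenomeMap
    qtn_site_index: list[np.ndarray]
    chrom: np.ndarray
    pos_bp: np.ndarray
    alpha: np.ndarray
    editable: np.ndarray | None = None
    _chrom_offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        per_chrom = [idx.size for idx in self.qtn_site_index]
        if len(set(per_chrom)) > 1:
            raise ValueError("equal QTN count per chromosome required")
        if not (self.chrom.size == self.pos_bp.size == self.alpha.size == sum(per_chrom)):
            raise ValueError("inconsistent QTN array lengths")
        if np.any(self.alpha == 0.0):
            raise ValueError("zero allele-substitution effects are not allowed")
        self._chrom_offsets = np.concatenate([[0], np.cumsum(per_chrom)])

    @property
    def n_qtn(self) -> int:
        return int(self.alpha.size)

    @property
    def favourable(self) -> np.ndarray:
        """Favourable allele per QTN: 1 where alpha > 0, else 0."""
        return (self.alpha > 0).astype(np.uint8)

    @property
    def gpos_m(self) -> np.ndarray:
        """Genetic position of each QTN in Morgans within its chromosome."""
        return self.genome.bp_to_morgans(self.pos_bp)

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self._chrom_offsets[c]), int(self._chrom_offsets[c + 1]))

    def tbv_of(self, genomes: np.ndarray) -> np.ndarray:
        """TBV for a ``(n, 2, n_qtn)`` genome array (or a single ``(2, n_qtn)``)."""
        return compute_tbv(genomes, self)

    def favourable_dosage(self, genomes: np.ndarray) -> np.ndarray:
        """Count of favourable alleles per individual per QTN, ``(n, n_qtn)``."""
        d1 = genomes.sum(axis=-2)
        fav = self.favourable
        return np.where(fav == 1, d1, 2 - d1)

    def top_qtn(self, k: int = 20, restrict: np.ndarray | None = None) -> np.ndarray:
        """Indices of the ``k`` largest-|alpha| QTN, optionally within a mask.

        Ties are broken by ascending QTN index.
        """
        idx = np.arange(self.n_qtn) if restrict is None else np.flatnonzero(restrict)
        order = np.lexsort((idx, -np.abs(self.alpha[idx])))
        return idx[order[:k]]

    def to_frame(self) -> pd.DataFrame:
        """Trait architecture as a tidy table (one row per QTN)."""
        return pd.DataFrame(
            {
                "chromosome": self.chrom + 1,
                "position_bp": self.pos_bp,
                "alpha": self.alpha,
                "favourable_allele": self.favourable,
                "editable": (
                    np.full(self.n_qtn, np.nan) if self.editable is None else self.editable.astype(int)
                ),
            }
        )


def build_architecture(
    founders: FounderHaplotypes,
    n_qtn: int = 10_000,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> TraitArchitecture:
    """Sample QTN and effects from founder haplotypes into an architecture."""
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    site_index = sample_qtn(founders, n_qtn, rng)
    chrom = np.concatenate([np.full(idx.size, c, dtype=np.int64) for c, idx in enumerate(site_index)])
    pos_bp = np.concatenate([founders.positions_bp[c][idx] for c, idx in enumerate(site_index)])
    alpha = sample_effects(n_qtn, rng)
    return TraitArchitecture(
        genome=founders.genome, qtn_site_index=site_index, chrom=chrom, pos_bp=pos_bp, alpha=alpha
    )


def compute_tbv(genomes: np.ndarray, arch: TraitArchitecture) -> np.ndarray | float:
    """TBV under allele-1 dosage coding: ``sum_i alpha_i * dosage_i``.

    Accepts a single genome ``(2, n_qtn)`` or a batch ``(n, 2, n_qtn)``.
    """
    genomes = np.asarray(genomes)
    if genomes.shape[-1] != arch.n_qtn:
        raise ValueError(f"genome has {genomes.shape[-1]} loci, architecture has {arch.n_qtn}")
    dosage = genomes.sum(axis=-2, dtype=np.int64)
    out = dosage @ arch.alpha
    return float(out) if out.ndim == 0 else out


def freeze_editability(arch: TraitArchitecture, population) -> np.ndarray:
    """Freeze the editability mask: QTN segregating in generation 0.

    Only QTN at which both alleles are present among the generation-0
    individuals may ever be edited; this keeps the genetic variation
    available to selection identical between edited and unedited
    scenarios.  The mask is computed once, at generation 0, and is
    immutable thereafter — repeated calls return the stored mask.
    """
    if arch.editable is not None:
        return arch.editable.copy()
    if population.generation != 0:
        raise ValueError(
            f"editability is defined by segregation at generation 0, got generation {population.generation}"
        )
    counts = population.genomes.sum(axis=(0, 1), dtype=np.int64)
    n_alleles = 2 * population.genomes.shape[0]
    arch.editable = (counts > 0) & (counts < n_alleles)
    return arch.editable.copy()
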