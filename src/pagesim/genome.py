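"""Genome map and demographic history.

The simulated genome is a set of equally sized chromosomes with a uniform
genetic map (constant cM/bp within a chromosome).  Effective population
size over time is a piecewise-linear function of generations ago, anchored
at a small number of (time, Ne) points; beyond the oldest anchor the size
is held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "DemographySchedule", "ne_at", "DEFAULT_GENOME", "DEFAULT_DEMOGRAPHY"]


@dataclass(frozen=True)
class GenomeMap:
    """Uniform multi-chromosome genome map.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes, all with identical lengths.
    chrom_length_cm
        Genetic length of each chromosome in centimorgans.
    chrom_length_bp
        Physical length of each chromosome in base pairs.
    mu
        Per-site, per-generation mutation rate.
    """

    n_chromosomes: int = 10
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 100_000_000
    mu: float = 2.5e-8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom_length_cm <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome lengths must be strictly positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")

    @property
    def chrom_length_morgans(self) -> float:
        return self.chrom_length_cm / 100.0

    @property
    def recomb_per_bp(self) -> float:
        """Uniform recombination rate, Morgans per base pair."""
        return self.chrom_length_morgans / self.chrom_length_bp

    def bp_to_morgans(self, pos_bp: np.ndarray) -> np.ndarray:
        """Map 1-based physical positions to genetic positions in Morgans."""
        return (np.asarray(pos_bp, dtype=float) - 0.5) * self.recomb_per_bp


@dataclass(frozen=True)
class DemographySchedule:
    """Piecewise-linear effective population size history.

    ``anchors`` is an ordered sequence of ``(generations_ago, Ne)`` pairs
    with strictly increasing times.  Ne is linearly interpolated between
    anchors and held constant beyond the oldest anchor.
    """

    anchors: tuple[tuple[float, float], ...] = (
        (0, 100.0),
        (1_000, 1_256.0),
        (10_000, 4_350.0),
        (100_000, 43_500.0),
    )

    def __post_init__(self) -> None:
        if len(self.anchors) < 1:
            raise ValueError("at least one anchor required")
        times = [t for t, _ in self.anchors]
        sizes = [n for _, n in self.anchors]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("anchor times must be strictly increasing")
        if times[0] < 0:
            raise ValueError("anchor times must be non-negative")
        if any(n <= 0 for n in sizes):
            raise ValueError("Ne must be strictly positive at every anchor")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.anchors], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.anchors], dtype=float)

    def ne_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Effective population size ``t`` generations ago."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("generations ago must be non-negative")
        out = np.interp(t_arr, self.times, self.sizes)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def ne_at(t: float | np.ndarray, schedule: DemographySchedule) -> float | np.ndarray:
    """Module-level convenience wrapper for :meth:`DemographySchedule.ne_at`."""
    return schedule.ne_at(t)


DEFAULT_GENOME = GenomeMap()
DEFAULT_DEMOGRAPHY = DemographySchedule()
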