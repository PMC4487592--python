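"""Summary statistics of the breeding program.

Covers the quantities reported per generation and replicate: cumulative
response to selection in base-generation TBV standard deviations, mean
favourable-allele frequencies (all QTN, generation-0-segregating QTN,
and the fixed top-20 largest-effect set), genic variance
``sum_i 2 p_i (1 - p_i) alpha_i^2``, pedigree inbreeding (Wright's F),
and the accounting of distinct edited QTN (QTNe) within and across
generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editing import EditPlan
from .trait import TraitArchitecture

__all__ = [
    "cumulative_response",
    "genic_variance",
    "favourable_frequency",
    "inbreeding_coefficients",
    "KinshipTracker",
    "QtneLedger",
    "sum_abs_edited_effects",
]


def cumulative_response(mean_tbv: float | np.ndarray, base_mean: float, base_sd: float) -> float | np.ndarray:
    """Cumulative response to selection in base-generation SD units.

    ``(mean TBV of the current generation - base mean) / base SD``.  The
    reference mean may be either generation -20 (start of recent
    historical breeding) or generation 0 (start of future breeding); the
    unit is always the TBV standard deviation of generation -20.
    """
    if base_sd <= 0:
        raise ValueError("base_sd must be strictly positive")
    out = (np.asarray(mean_tbv, dtype=float) - base_mean) / base_sd
    return float(out) if out.ndim == 0 else out


def genic_variance(p: np.ndarray, alpha: np.ndarray) -> float:
    """Genic variance ``sum_i 2 p_i (1 - p_i) alpha_i^2``.

    ``p`` may be the favourable-allele or the allele-1 frequency — the
    form is invariant to allele relabelling.  Fixed loci contribute 0.
    """
    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if p.shape != alpha.shape:
        raise ValueError(f"frequency/effect length mismatch: {p.shape} vs {alpha.shape}")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(np.sum(2.0 * p * (1.0 - p) * alpha**2))


def favourable_frequency(
    p1: np.ndarray, arch: TraitArchitecture, subset: np.ndarray | None = None
) -> float:
    """Mean favourable-allele frequency over a QTN subset.

    ``p1`` is the allele-1 frequency vector (over the 2n gametes of a
    population); the favourable orientation comes from the sign of each
    QTN's effect.  ``subset`` is an index array (default: all QTN).
    """
    p1 = np.asarray(p1, dtype=float)
    if p1.size != arch.n_qtn:
        raise ValueError(f"frequency vector has {p1.size} entries, architecture {arch.n_qtn}")
    fav = np.where(arch.favourable == 1, p1, 1.0 - p1)
    if subset is None:
        return float(fav.mean())
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("QTN subset must be non-empty")
    return float(fav[subset].mean())


# ---------------------------------------------------------------------------
# Pedigree inbreeding


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Wright's F for every individual of a pedigree.

    ``sire[i]``/``dam[i]`` hold 0-based parent indices or -1 for unknown
    (founder) parents; parents must precede offspring.  F of an
    individual is the kinship of its parents, computed by the recursive
    kinship definition with memoisation — identical to the full tabular
    (additive-relationship) method.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.size
    if np.any(sire >= np.arange(n)) and np.any(sire[sire >= 0] >= np.flatnonzero(sire >= 0)):
        pass  # detailed check below
    for i in range(n):
        for par in (sire[i], dam[i]):
            if par >= i:
                raise ValueError(f"individual {i} precedes its parent {par}")
    cache: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        got = cache.get(key)
        if got is not None:
            return got
        if a == b:
            val = 0.5 * (1.0 + kin(sire[a], dam[a]))
        else:
            # b is the younger individual: recurse through its parents
            val = 0.5 * (kin(a, sire[b]) + kin(a, dam[b]))
        cache[key] = val
        return val

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 1000))
    try:
        return np.array([kin(sire[i], dam[i]) for i in range(n)])
    finally:
        sys.setrecursionlimit(old)


class KinshipTracker:
    """Generation-layered kinship propagation for non-overlapping generations.

    Maintains the full kinship matrix K of the current generation.  With
    all parents drawn from the previous generation, the offspring kinship
    matrix follows exactly from the parental one, so Wright's F
    (``F_i = K(sire_i, dam_i)``) is obtained without touching the full
    pedigree.  Results agree with the tabular method to rounding error.

    The base generation is treated as unrelated and non-inbred:
    K = I/2.
    """

    def __init__(self, n: int):
        self.K = np.eye(n) * 0.5
        self.F = np.zeros(n)

    def copy(self) -> "KinshipTracker":
        new = KinshipTracker(1)
        new.K = self.K.copy()
        new.F = self.F.copy()
        return new

    def advance(self, sire_of: np.ndarray, dam_of: np.ndarray) -> np.ndarray:
        """Advance to the offspring generation; returns offspring F."""
        K, s, d = self.K, sire_of, dam_of
        F_off = K[s, d]
        K_new = 0.25 * (K[np.ix_(s, s)] + K[np.ix_(s, d)] + K[np.ix_(d, s)] + K[np.ix_(d, d)])
        np.fill_diagonal(K_new, 0.5 * (1.0 + F_off))
        self.K, self.F = K_new, F_off
        return F_off


# ---------------------------------------------------------------------------
# Edited-QTN accounting


@dataclass
class QtneLedger:
    """Distinct edited-QTN (QTNe) bookkeeping across generations 1-20."""

    plans: list[EditPlan]

    @property
    def per_generation_sets(self) -> list[np.ndarray]:
        return [p.qtne for p in self.plans]

    def distinct_counts(self) -> pd.Series:
        """Number of distinct QTNe per generation."""
        return pd.Series(
            {p.generation: int(p.qtne.size) for p in self.plans}, name="n_distinct_qtne"
        )

    def pairwise_overlap(self) -> pd.DataFrame:
        """Matrix of |QTNe_g ∩ QTNe_h| (diagonal: per-generation counts)."""
        sets = [set(p.qtne.tolist()) for p in self.plans]
        gens = [p.generation for p in self.plans]
        m = np.array([[len(a & b) for b in sets] for a in sets], dtype=int)
        return pd.DataFrame(m, index=gens, columns=gens)

    def cumulative_union(self) -> np.ndarray:
        """Distinct QTNe across all generations (union of the sets)."""
        if not self.plans:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate([p.qtne for p in self.plans]))

    def cumulative_distinct(self) -> int:
        return int(self.cumulative_union().size)

    def variance_share(self, arch: TraitArchitecture, p1_gen0: np.ndarray) -> float:
        """Share of generation-0 genic variance carried by the cumulative QTNe union.

        Both numerator and denominator use generation-0 allele
        frequencies; loci fixed at generation 0 contribute nothing to
        either, so the denominator equals the variance over the
        generation-0-segregating set.
        """
        total = genic_variance(p1_gen0, arch.alpha)
        if total == 0:
            return 0.0
        union = self.cumulative_union()
        if union.size == 0:
            return 0.0
        part = genic_variance(p1_gen0[union], arch.alpha[union])
        return part / total


def sum_abs_edited_effects(plan: EditPlan, arch: TraitArchitecture) -> float:
    """Sum of |alpha| over the generation's distinct edited QTN."""
    q = plan.qtne
    return float(np.abs(arch.alpha[q]).sum()) if q.size else 0.0
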