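"""Promotion of alleles by genome editing (PAGE).

In each future generation the 25 selected sires are ranked by their
(pre-edit) TBV and a strategy-defined subset of them is germline-edited:
for each chosen sire, the editable QTN with the largest absolute
allele-substitution effects at which the sire is not already homozygous
for the favourable allele are set to homozygous favourable.  Editing is
assumed perfectly precise (no off-target changes, 100% success) and the
edited alleles are transmitted through meiosis like any other allele.

Only QTN that segregated in generation 0 are editable, so scenarios with
and without PAGE compete on identical standing variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import Population
from .trait import TraitArchitecture

logger = logging.getLogger(__name__)

__all__ = [
    "SIRE_SUBSETS",
    "EditStrategy",
    "EditPlan",
    "choose_sires_to_edit",
    "choose_qtn_for_sire",
    "apply_edits",
    "plan_generation_edits",
]

#: subset code -> (number of sires edited, which end of the TBV ranking)
SIRE_SUBSETS: dict[str, tuple[int, str]] = {
    "A25se": (25, "top"),
    "T10se": (10, "top"),
    "B10se": (10, "bottom"),
    "T5se": (5, "top"),
}

EDITS_PER_SIRE_MENU = (0, 1, 5, 10, 20, 25, 50, 100)


@dataclass(frozen=True)
class EditStrategy:
    """Which sires to edit and how many QTN per sire.

    ``sire_subset`` is one of A25se (all 25 selected sires), T10se /
    T5se (top 10 / 5 by TBV) or B10se (bottom 10 by TBV).
    """

    sire_subset: str = "A25se"
    edits_per_sire: int = 0

    def __post_init__(self) -> None:
        if self.sire_subset not in SIRE_SUBSETS:
            raise ValueError(f"unknown sire subset {self.sire_subset!r}; choose from {sorted(SIRE_SUBSETS)}")
        if self.edits_per_sire < 0:
            raise ValueError("edits_per_sire must be >= 0")

    @property
    def subset_size(self) -> int:
        return SIRE_SUBSETS[self.sire_subset][0]

    @property
    def edits_per_generation(self) -> int:
        return self.edits_per_sire * self.subset_size

    @property
    def name(self) -> str:
        if self.edits_per_sire == 0:
            return "GS_only"
        return f"{self.sire_subset}_{self.edits_per_sire}"

    @classmethod
    def from_name(cls, name: str) -> "EditStrategy":
        """Parse ``'<subset>_<edits_per_sire>'`` (e.g. T5se_100) or ``GS_only``."""
        if name in ("GS_only", "GS-only", "gs_only"):
            return cls("A25se", 0)
        try:
            subset, n = name.rsplit("_", 1)
            return cls(subset, int(n))
        except (ValueError, TypeError):
            raise ValueError(f"cannot parse scenario name {name!r}") from None


@dataclass
class EditPlan:
    """Realised edits for one generation.

    ``per_sire`` maps sire id to the ordered QTN indices edited in that
    sire; ``qtne`` is the generation's distinct edited-QTN set (a QTN
    counts as edited if it was edited in at least one sire).
    """

    generation: int
    per_sire: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def qtne(self) -> np.ndarray:
        if not self.per_sire:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate(list(self.per_sire.values())))

    @property
    def n_edits(self) -> int:
        return int(sum(v.size for v in self.per_sire.values()))

    def to_frame(self, arch: TraitArchitecture, pre_edit_genotypes: dict[int, np.ndarray] | None = None) -> pd.DataFrame:
        rows = []
        for sire_id, qtn in self.per_sire.items():
            for j, q in enumerate(qtn):
                rows.append(
                    {
                        "generation": self.generation,
                        "sire_id": sire_id,
                        "qtn_id": int(q),
                        "alpha": arch.alpha[q],
                        "pre_edit_genotype": (
                            pre_edit_genotypes[sire_id][j] if pre_edit_genotypes else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows, columns=["generation", "sire_id", "qtn_id", "alpha", "pre_edit_genotype"])


def choose_sires_to_edit(pop: Population, selected_sires: np.ndarray, strategy: EditStrategy) -> np.ndarray:
    """Pick the strategy's subset of the 25 selected sires.

    ``selected_sires`` are positional indices ordered by TBV descending
    with ties already broken by ascending id (as produced by
    :func:`~pagesim.breeding.select_parents`).
    """
    n, end = SIRE_SUBSETS[strategy.sire_subset]
    if selected_sires.size < n:
        raise ValueError(f"{strategy.sire_subset} needs {n} selected sires, have {selected_sires.size}")
    return selected_sires[:n] if end == "top" else selected_sires[-n:]


def choose_qtn_for_sire(
    pop: Population, sire: int, arch: TraitArchitecture, n_edits: int
) -> np.ndarray:
    """QTN to edit in one sire, largest |alpha| first.

    Candidates are the editable (generation-0-segregating) QTN at which
    the sire carries at least one unfavourable allele; they are ranked by
    |alpha| descending with ties broken by ascending QTN index.  If fewer
    candidates exist than ``n_edits``, the short list is returned.
    """
    if arch.editable is None:
        raise ValueError("editability mask not frozen; call freeze_editability at generation 0 first")
    fav_dosage = arch.favourable_dosage(pop.genomes[sire][None])[0]
    candidates = np.flatnonzero(arch.editable & (fav_dosage < 2))
    if candidates.size < n_edits:
        logger.debug(
            "sire %d: only %d editable candidates for %d requested edits",
            int(pop.ids[sire]), candidates.size, n_edits,
        )
    order = np.lexsort((candidates, -np.abs(arch.alpha[candidates])))
    return candidates[order[:n_edits]]


def apply_edits(pop: Population, sire: int, qtn_list: np.ndarray, arch: TraitArchitecture) -> None:
    """Set both gametic alleles to the favourable allele at the listed QTN.

    Mutates the sire's genome in place, records the edit on the
    individual and recomputes its TBV, so all subsequent gametes are
    drawn from the edited genome.
    """
    if qtn_list.size == 0:
        return
    if arch.editable is None or not np.all(arch.editable[qtn_list]):
        raise ValueError("attempt to edit a QTN outside the frozen editable set")
    fav = arch.favourable[qtn_list]
    pop.genomes[sire, 0, qtn_list] = fav
    pop.genomes[sire, 1, qtn_list] = fav
    pop.tbv[sire] = arch.tbv_of(pop.genomes[sire])
    sire_id = int(pop.ids[sire])
    prev = pop.edits.get(sire_id, np.array([], dtype=np.int64))
    pop.edits[sire_id] = np.concatenate([prev, qtn_list.astype(np.int64)])


def plan_generation_edits(
    pop: Population,
    selected_sires: np.ndarray,
    strategy: EditStrategy,
    arch: TraitArchitecture,
    generation: int,
    apply: bool = True,
) -> EditPlan:
    """Choose and (by default) apply this generation's edits.

    ``generation`` is the index of the offspring generation the edited
    sires will produce; PAGE operates only in the future phase
    (generation >= 1).  Sires must already have been selected on their
    pre-edit TBV.
    """
    if generation < 1:
        raise ValueError("PAGE is applied only in future generations (>= 1)")
    plan = EditPlan(generation=generation)
    if strategy.edits_per_sire == 0:
        return plan
    for sire in choose_sires_to_edit(pop, selected_sires, strategy):
        qtn = choose_qtn_for_sire(pop, int(sire), arch, strategy.edits_per_sire)
        plan.per_sire[int(pop.ids[sire])] = qtn
        if apply:
            apply_edits(pop, int(sire), qtn, arch)
    return plan
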