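"""Scenario orchestration: configuration, replicates, paired branches, summaries.

A replicate runs the whole scheme once: coalescent founders, trait
architecture, the base population at generation -20, 20 generations of
historical selection up to generation 0, then — from the identical
generation-0 state — one future branch per scenario (GS only and each
GS + PAGE strategy) for 20 further generations.  Pairing all branches on
the same history makes between-scenario contrasts (e.g. the relative
response ratio) much less noisy than independent runs.

Randomness: the master seed spawns one ``SeedSequence`` per replicate;
each replicate spawns independent streams for founders, trait, base
population and the historical phase, plus a single future-phase stream
that every branch restarts identically.  Editing consumes no random
numbers, so a zero-edit PAGE branch is bitwise identical to GS only,
and adding a scenario never perturbs another scenario's randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import breeding, editing, metrics
from .breeding import Population
from .editing import EditPlan, EditStrategy
from .founders import FounderHaplotypes, build_base_population, simulate_founder_haplotypes
from .genome import DemographySchedule, GenomeMap
from .metrics import KinshipTracker, QtneLedger
from .trait import TraitArchitecture, build_architecture, freeze_editability

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "ReplicateResult", "run_replicate", "run_experiment", "summarize", "relative_response"]

TOP_K = 20  # size of the tracked largest-effect QTN set


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of a simulation experiment."""

    genome: GenomeMap = field(default_factory=GenomeMap)
    demography: DemographySchedule = field(default_factory=DemographySchedule)
    n_qtn: int = 10_000
    n_founder_haplotypes: int = 1000
    population_size: int = 1000
    n_sires: int = 25
    n_dams: int = 500
    historical_generations: int = 20  # advances from generation -20 to 0
    future_generations: int = 20
    scenarios: tuple[str, ...] = ("GS_only", "A25se_20")
    n_replicates: int = 10
    master_seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_qtn % self.genome.n_chromosomes:
            raise ValueError(
                f"n_qtn={self.n_qtn} not divisible by n_chromosomes={self.genome.n_chromosomes}"
            )
        if self.population_size % 2:
            raise ValueError("population_size must be even (half male, half female)")
        n_dams, n_sires = self.n_dams, self.n_sires
        if self.population_size % n_dams or self.population_size % n_sires or n_dams % n_sires:
            raise ValueError(
                f"equal-contribution mating needs population_size divisible by n_dams and "
                f"n_dams divisible by n_sires (got {self.population_size}/{n_dams}/{n_sires})"
            )
        if self.n_founder_haplotypes < 2 or self.n_founder_haplotypes % 2:
            raise ValueError("n_founder_haplotypes must be even and >= 2")
        for name in self.scenarios:
            EditStrategy.from_name(name)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def strategies(self) -> dict[str, EditStrategy]:
        return {name: EditStrategy.from_name(name) for name in self.scenarios}

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        g = d.get("genome", {})
        genome = GenomeMap(
            n_chromosomes=int(g.get("n_chromosomes", 10)),
            chrom_length_cm=float(g.get("chrom_length_cm", 100.0)),
            chrom_length_bp=int(g.get("chrom_length_bp", 100_000_000)),
            mu=float(g.get("mutation_rate", 2.5e-8)),
        )
        dem = d.get("demography", {})
        anchors = dem.get("anchors")
        demography = (
            DemographySchedule(tuple((float(t), float(n)) for t, n in anchors))
            if anchors
            else DemographySchedule()
        )
        p = d.get("population", {})
        prog = d.get("program", {})
        return cls(
            genome=genome,
            demography=demography,
            n_qtn=int(d.get("trait", {}).get("n_qtn", 10_000)),
            n_founder_haplotypes=int(g.get("n_founder_haplotypes", 1000)),
            population_size=int(p.get("size", 1000)),
            n_sires=int(p.get("n_sires", 25)),
            n_dams=int(p.get("n_dams", 500)),
            historical_generations=int(prog.get("historical_generations", 20)),
            future_generations=int(prog.get("future_generations", 20)),
            scenarios=tuple(prog.get("scenarios", ("GS_only", "A25se_20"))),
            n_replicates=int(prog.get("n_replicates", 10)),
            master_seed=int(prog.get("master_seed", 1)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "genome": {
                "n_chromosomes": self.genome.n_chromosomes,
                "chrom_length_cm": self.genome.chrom_length_cm,
                "chrom_length_bp": self.genome.chrom_length_bp,
                "mutation_rate": self.genome.mu,
                "n_founder_haplotypes": self.n_founder_haplotypes,
            },
            "demography": {"anchors": [list(a) for a in self.demography.anchors]},
            "trait": {"n_qtn": self.n_qtn},
            "population": {"size": self.population_size, "n_sires": self.n_sires, "n_dams": self.n_dams},
            "program": {
                "historical_generations": self.historical_generations,
                "future_generations": self.future_generations,
                "scenarios": list(self.scenarios),
                "n_replicates": self.n_replicates,
                "master_seed": self.master_seed,
            },
        }


class _Trace:
    """Per-branch accumulator of generation-level state."""

    def __init__(self) -> None:
        self.generation: list[int] = []
        self.mean_tbv: list[float] = []
        self.p1: list[np.ndarray] = []
        self.f_mean: list[float] = []
        self.pedigree: list[pd.DataFrame] = []

    def record(self, pop: Population, f_mean: float) -> None:
        self.generation.append(pop.generation)
        self.mean_tbv.append(float(pop.tbv.mean()))
        self.p1.append(pop.allele1_frequency())
        self.f_mean.append(f_mean)
        self.pedigree.append(pop.pedigree_frame())


@dataclass
class ReplicateResult:
    """All traces and edit ledgers of one replicate."""

    replicate: int
    config: ScenarioConfig
    arch: TraitArchitecture
    historical: _Trace
    branches: dict[str, _Trace]
    ledgers: dict[str, QtneLedger]
    base_stats: dict[str, float]  # mean/sd of TBV at generations -20 and 0
    top20: np.ndarray
    p1_gen0: np.ndarray
    founder_segregating_sites: int = 0

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy per-(scenario, generation) metrics table for this replicate."""
        arch = self.arch
        seg0 = np.flatnonzero(arch.editable) if arch.editable is not None else None
        rows = []

        def emit(scenario: str, trace: _Trace, plans: dict[int, EditPlan]):
            for i, gen in enumerate(trace.generation):
                p1 = trace.p1[i]
                plan = plans.get(gen)
                rows.append(
                    {
                        "replicate": self.replicate,
                        "scenario": scenario,
                        "generation": gen,
                        "mean_tbv": trace.mean_tbv[i],
                        "response_base_m20": metrics.cumulative_response(
                            trace.mean_tbv[i], self.base_stats["mean_m20"], self.base_stats["sd_m20"]
                        ),
                        # both response bases are expressed in units of the
                        # generation -20 TBV standard deviation; only the
                        # reference mean switches to generation 0
                        "response_base_0": metrics.cumulative_response(
                            trace.mean_tbv[i], self.base_stats["mean_0"], self.base_stats["sd_m20"]
                        ),
                        "freq_all_qtn": metrics.favourable_frequency(p1, arch),
                        "freq_seg0": (
                            metrics.favourable_frequency(p1, arch, seg0) if seg0 is not None else np.nan
                        ),
                        "freq_top20": metrics.favourable_frequency(p1, arch, self.top20),
                        "genic_var_all": metrics.genic_variance(p1, arch.alpha),
                        "genic_var_top20": metrics.genic_variance(p1[self.top20], arch.alpha[self.top20]),
                        "mean_f": trace.f_mean[i],
                        "n_distinct_qtne": plan.qtne.size if plan is not None else 0,
                        "sum_abs_alpha_qtne": (
                            metrics.sum_abs_edited_effects(plan, arch) if plan is not None else 0.0
                        ),
                    }
                )

        emit("historical", self.historical, {})
        for name, trace in self.branches.items():
            emit(name, trace, {p.generation: p for p in self.ledgers[name].plans})
        return pd.DataFrame(rows)

    def qtne_summary(self) -> pd.DataFrame:
        rows = []
        for name, ledger in self.ledgers.items():
            rows.append(
                {
                    "replicate": self.replicate,
                    "scenario": name,
                    "cumulative_distinct_qtne": ledger.cumulative_distinct(),
                    "qtne_variance_share": ledger.variance_share(self.arch, self.p1_gen0),
                }
            )
        return pd.DataFrame(rows)

    def pedigree_frame(self, scenario: str | None = None) -> pd.DataFrame:
        frames = list(self.historical.pedigree)
        if scenario is not None:
            frames += self.branches[scenario].pedigree[1:]  # skip duplicated generation 0
        return pd.concat(frames, ignore_index=True)


def run_replicate(
    config: ScenarioConfig,
    replicate_seed: np.random.SeedSequence,
    replicate_index: int = 0,
    founders: FounderHaplotypes | None = None,
) -> ReplicateResult:
    """Run one full replicate: founders -> history -> paired future branches."""
    founder_ss, trait_ss, base_ss, hist_ss, future_ss = replicate_seed.spawn(5)

    if founders is None:
        logger.info("replicate %d: simulating founder haplotypes", replicate_index)
        founders = simulate_founder_haplotypes(
            config.genome, config.demography, config.n_founder_haplotypes, seed=founder_ss
        )
    arch = build_architecture(founders, config.n_qtn, seed=np.random.default_rng(trait_ss))
    base = build_base_population(
        founders,
        arch,
        config.population_size,
        seed=np.random.default_rng(base_ss),
        generation=-config.historical_generations,
    )

    # -- historical phase ---------------------------------------------------
    hist_rng = np.random.default_rng(hist_ss)
    kin = KinshipTracker(base.n_individuals)
    hist_trace = _Trace()

    def recorder(pop: Population, plan):
        nonlocal kin
        if plan is not None:
            kin.advance(plan.sire_of, plan.dam_of)
        hist_trace.record(pop, float(kin.F.mean()))

    pop0 = breeding.run_historical(
        base,
        config.genome,
        arch,
        hist_rng,
        n_generations=config.historical_generations,
        n_sires=config.n_sires,
        n_dams=config.n_dams,
        recorder=recorder,
    )
    freeze_editability(arch, pop0)
    top20 = arch.top_qtn(TOP_K, restrict=arch.editable)
    p1_gen0 = pop0.allele1_frequency()
    base_stats = {
        "mean_m20": float(base.tbv.mean()),
        "sd_m20": float(base.tbv.std()),  # population SD: the base generation is the whole population
        "mean_0": float(pop0.tbv.mean()),
        "sd_0": float(pop0.tbv.std()),
    }
    kin_gen0 = kin

    # -- future branches (paired on the generation-0 state) -----------------
    branches: dict[str, _Trace] = {}
    ledgers: dict[str, QtneLedger] = {}
    for name, strategy in config.strategies.items():
        rng = np.random.default_rng(future_ss)  # identical stream for every branch
        pop = pop0.copy()
        bkin = kin_gen0.copy()
        trace = _Trace()
        trace.record(pop, float(bkin.F.mean()))
        plans: list[EditPlan] = []
        for g in range(1, config.future_generations + 1):
            sires, dams = breeding.select_parents(pop, config.n_sires, config.n_dams)
            plan_edits = editing.plan_generation_edits(pop, sires, strategy, arch, generation=g)
            if strategy.edits_per_sire > 0:
                plans.append(plan_edits)
            mplan = breeding.make_mating_plan(sires, dams, config.population_size, rng)
            pop = breeding.advance_generation(pop, mplan, config.genome, arch, rng)
            bkin.advance(mplan.sire_of, mplan.dam_of)
            trace.record(pop, float(bkin.F.mean()))
        branches[name] = trace
        ledgers[name] = QtneLedger(plans=plans)
        logger.info("replicate %d: branch %s done", replicate_index, name)

    return ReplicateResult(
        replicate=replicate_index,
        config=config,
        arch=arch,
        historical=hist_trace,
        branches=branches,
        ledgers=ledgers,
        base_stats=base_stats,
        top20=top20,
        p1_gen0=p1_gen0,
        founder_segregating_sites=founders.total_segregating_sites,
    )


def run_experiment(
    config: ScenarioConfig,
    n_replicates: int | None = None,
    founders: FounderHaplotypes | None = None,
) -> list[ReplicateResult]:
    """Run all replicates serially with deterministically derived seeds."""
    n = config.n_replicates if n_replicates is None else n_replicates
    root = np.random.SeedSequence(config.master_seed)
    rep_seeds = root.spawn(n)
    return [
        run_replicate(config, rep_seeds[i], replicate_index=i, founders=founders) for i in range(n)
    ]


def relative_response(results: Sequence[ReplicateResult], baseline: str = "GS_only") -> pd.DataFrame:
    """Per-replicate GS+PAGE / GS-only response ratio at the final generation.

    Responses use generation 0 as base; ratios are formed within a
    replicate (paired branches) and then summarised over replicates.
    """
    rows = []
    for res in results:
        frame = res.metrics_frame()
        final = frame[frame.generation == frame.generation.max()]
        base_val = final.loc[final.scenario == baseline, "response_base_0"]
        if base_val.empty:
            raise ValueError(f"baseline scenario {baseline!r} missing from results")
        base_val = float(base_val.iloc[0])
        for name in res.branches:
            val = float(final.loc[final.scenario == name, "response_base_0"].iloc[0])
            rows.append({"replicate": res.replicate, "scenario": name, "relative_response": val / base_val})
    return pd.DataFrame(rows)


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-based confidence interval over replicates."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if x.size < 2:
        return m, np.nan, np.nan
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    if se == 0:
        return m, m, m
    tq = stats.t.ppf(0.5 + level / 2, x.size - 1)
    return m, m - tq * se, m + tq * se


def summarize(results: Sequence[ReplicateResult], level: float = 0.95) -> dict[str, pd.DataFrame]:
    """Replicate-level means and confidence intervals.

    Returns tidy tables: ``metrics`` (per scenario x generation x metric),
    ``relative_response`` and ``qtne`` (per scenario).
    """
    all_metrics = pd.concat([r.metrics_frame() for r in results], ignore_index=True)
    value_cols = [
        c for c in all_metrics.columns if c not in ("replicate", "scenario", "generation")
    ]
    rows = []
    for (scenario, gen), grp in all_metrics.groupby(["scenario", "generation"]):
        for col in value_cols:
            m, lo, hi = _mean_ci(grp[col].to_numpy(), level)
            rows.append(
                {"scenario": scenario, "generation": gen, "metric": col, "mean": m, "ci_low": lo, "ci_high": hi}
            )
    metrics_summary = pd.DataFrame(rows)

    rel = relative_response(results)
    rel_rows = []
    for scenario, grp in rel.groupby("scenario"):
        m, lo, hi = _mean_ci(grp["relative_response"].to_numpy(), level)
        rel_rows.append({"scenario": scenario, "mean": m, "ci_low": lo, "ci_high": hi})

    qtne = pd.concat([r.qtne_summary() for r in results], ignore_index=True)
    q_rows = []
    for scenario, grp in qtne.groupby("scenario"):
        for col in ("cumulative_distinct_qtne", "qtne_variance_share"):
            m, lo, hi = _mean_ci(grp[col].to_numpy(), level)
            q_rows.append({"scenario": scenario, "metric": col, "mean": m, "ci_low": lo, "ci_high": hi})

    return {
        "metrics": metrics_summary,
        "metrics_raw": all_metrics,
        "relative_response": pd.DataFrame(rel_rows),
        "relative_response_raw": rel,
        "qtne": pd.DataFrame(q_rows),
        "qtne_raw": qtne,
    }
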