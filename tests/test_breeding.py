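"""Selection, mating design, meiosis and generation advance."""

import numpy as np
import pytest

from pagesim.breeding import (
    MatingPlan,
    _drop_gametes,
    advance_generation,
    make_mating_plan,
    meiosis,
    run_historical,
    select_parents,
)
from pagesim.genome import GenomeMap
from pagesim.trait import build_architecture

from conftest import make_arch, make_founders, make_population


class TestSelectParents:
    def test_top_by_tbv(self, small_arch):
        pop = make_population(small_arch, n=20, seed=0)
        sires, dams = select_parents(pop, n_sires=3, n_dams=5)
        males = pop.males
        best = males[np.argsort(-pop.tbv[males])][:3]
        assert set(sires.tolist()) == set(best.tolist())
        assert list(pop.tbv[sires]) == sorted(pop.tbv[sires], reverse=True)

    def test_all_females_selected_when_quota_full(self, small_arch):
        pop = make_population(small_arch, n=20, seed=0)
        _, dams = select_parents(pop, n_sires=2, n_dams=10)
        assert set(dams.tolist()) == set(pop.females.tolist())

    def test_tie_break_by_ascending_id(self, small_arch):
        pop = make_population(small_arch, n=20, seed=0)
        pop.tbv[:] = 1.0
        sires, _ = select_parents(pop, n_sires=3, n_dams=5)
        assert pop.ids[sires].tolist() == [1, 2, 3]

    def test_insufficient_candidates_rejected(self, small_arch):
        pop = make_population(small_arch, n=20, seed=0)
        with pytest.raises(ValueError):
            select_parents(pop, n_sires=11, n_dams=5)


class TestMatingPlan:
    def test_default_quotas(self, small_arch):
        pop = make_population(small_arch, n=20, seed=1)
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=2)
        assert plan.n_offspring == 20
        sire_counts = np.unique(plan.sire_of, return_counts=True)[1]
        dam_counts = np.unique(plan.dam_of, return_counts=True)[1]
        assert np.all(sire_counts == 10)
        assert np.all(dam_counts == 2)

    def test_full_sibs_share_sire(self, small_arch):
        pop = make_population(small_arch, n=20, seed=1)
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=3)
        for dam in np.unique(plan.dam_of):
            assert np.unique(plan.sire_of[plan.dam_of == dam]).size == 1

    def test_non_integral_quota_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_mating_plan(np.arange(3), np.arange(10), 20, seed=0)

    def test_small_example_quotas(self):
        plan = make_mating_plan(np.arange(5), np.arange(5, 15), 20, seed=4)
        assert np.all(np.unique(plan.sire_of, return_counts=True)[1] == 4)
        assert np.all(np.unique(plan.dam_of, return_counts=True)[1] == 2)


class TestMeiosis:
    def test_zero_crossover_gamete_copies_a_strand(self, small_genome):
        """With a 0-length genetic map there are no crossovers."""
        genome = GenomeMap(n_chromosomes=1, chrom_length_cm=1e-9, chrom_length_bp=1_000_000)
        fh = make_founders(genome, sites_per_chrom=30, seed=5)
        arch = build_architecture(fh, 10, seed=6)
        parent = np.zeros((2, 10), dtype=np.uint8)
        parent[1] = 1
        rng = np.random.default_rng(0)
        for _ in range(20):
            gamete = meiosis(parent, genome, arch, rng)
            assert np.all(gamete == 0) or np.all(gamete == 1)

    def test_haldane_recombination_fraction(self):
        """Two loci d Morgans apart recombine at (1 - exp(-2d))/2."""
        rng = np.random.default_rng(12)
        n = 200_000
        for d in (0.25, 0.5):
            parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
            haps = np.broadcast_to(parent, (n, 2, 2))
            gpos = np.array([0.1, 0.1 + d])
            gam = _drop_gametes(haps, gpos, 1.0, rng)
            frac = float((gam[:, 0] != gam[:, 1]).mean())
            expected = (1 - np.exp(-2 * d)) / 2
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 5 * se

    def test_mean_crossovers_equals_map_length(self):
        """Observed strand switches average ~1 per 1-Morgan chromosome.

        With one parental strand all-0 and the other all-1, every strand
        switch along a dense marker grid is visible as an allele switch;
        the count of switches estimates the crossover count (downward
        bias from double crossovers within a 0.01 M interval is <1%).
        """
        rng = np.random.default_rng(3)
        n = 100_000
        L = 100
        parent = np.vstack([np.zeros(L, np.uint8), np.ones(L, np.uint8)])[None]
        haps = np.broadcast_to(parent, (n, 2, L))
        gpos = np.linspace(0.005, 0.995, L)
        gam = _drop_gametes(haps, gpos, 1.0, rng)
        switches = (gam[:, 1:] != gam[:, :-1]).sum(axis=1)
        assert switches.mean() == pytest.approx(0.99, abs=0.03)


class TestAdvanceGeneration:
    def _setup(self, seed=7):
        genome = GenomeMap(n_chromosomes=2, chrom_length_bp=1_000_000)
        fh = make_founders(genome, n_hap=20, sites_per_chrom=30, seed=seed)
        arch = build_architecture(fh, 10, seed=seed + 1)
        pop = make_population(arch, n=20, seed=seed + 2)
        return genome, arch, pop

    def test_mendelian_consistency(self):
        """Offspring alleles at every QTN come from their recorded parents."""
        genome, arch, pop = self._setup()
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=8)
        off = advance_generation(pop, plan, genome, arch, np.random.default_rng(9))
        for i in range(off.n_individuals):
            s = plan.sire_of[i]
            d = plan.dam_of[i]
            for q in range(arch.n_qtn):
                assert off.genomes[i, 0, q] in pop.genomes[s, :, q]
                assert off.genomes[i, 1, q] in pop.genomes[d, :, q]

    def test_monomorphic_population_stays_monomorphic(self):
        genome, arch, pop = self._setup()
        pop.genomes[:] = 1
        pop.tbv = arch.tbv_of(pop.genomes)
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=1)
        off = advance_generation(pop, plan, genome, arch, np.random.default_rng(2))
        assert np.all(off.genomes == 1)
        assert np.unique(off.tbv).size == 1

    def test_deterministic_under_seed(self):
        genome, arch, pop = self._setup()
        sires, dams = select_parents(pop, 2, 10)
        outs = []
        for _ in range(2):
            plan = make_mating_plan(sires, dams, 20, seed=5)
            off = advance_generation(pop, plan, genome, arch, np.random.default_rng(6))
            outs.append(off.genomes.copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_sex_counts_exact(self):
        genome, arch, pop = self._setup()
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=5)
        off = advance_generation(pop, plan, genome, arch, np.random.default_rng(0))
        assert off.males.size == off.females.size == 10

    def test_pedigree_links_recorded(self):
        genome, arch, pop = self._setup()
        sires, dams = select_parents(pop, 2, 10)
        plan = make_mating_plan(sires, dams, 20, seed=5)
        off = advance_generation(pop, plan, genome, arch, np.random.default_rng(0))
        np.testing.assert_array_equal(off.sire, pop.ids[plan.sire_of])
        np.testing.assert_array_equal(off.dam, pop.ids[plan.dam_of])
        assert off.generation == pop.generation + 1


class TestRunHistorical:
    def test_generation_indices(self):
        genome = GenomeMap(n_chromosomes=2, chrom_length_bp=1_000_000)
        fh = make_founders(genome, n_hap=20, sites_per_chrom=30, seed=1)
        arch = build_architecture(fh, 10, seed=2)
        pop = make_population(arch, n=20, generation=-5, seed=3)
        gens = []
        final = run_historical(
            pop, genome, arch, np.random.default_rng(4), n_generations=5,
            n_sires=2, n_dams=10, recorder=lambda p, plan: gens.append(p.generation),
        )
        assert gens == [-5, -4, -3, -2, -1, 0]
        assert final.generation == 0

    def test_drift_has_zero_mean_tbv_change(self):
        """Without selection the expected TBV change is zero (drift only)."""
        genome = GenomeMap(n_chromosomes=2, chrom_length_bp=1_000_000)
        fh = make_founders(genome, n_hap=40, sites_per_chrom=60, seed=5)
        arch = build_architecture(fh, 40, seed=6)
        deltas = []
        for rep in range(40):
            pop = make_population(arch, n=40, generation=-3, seed=100 + rep)
            final = run_historical(
                pop, genome, arch, np.random.default_rng(200 + rep),
                n_generations=3, n_sires=4, n_dams=20, select=False,
            )
            deltas.append(final.tbv.mean() - pop.tbv.mean())
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 4 * se

    def test_selection_increases_tbv(self):
        genome = GenomeMap(n_chromosomes=2, chrom_length_bp=1_000_000)
        fh = make_founders(genome, n_hap=40, sites_per_chrom=60, seed=7)
        arch = build_architecture(fh, 40, seed=8)
        pop = make_population(arch, n=40, generation=-5, seed=9)
        final = run_historical(
            pop, genome, arch, np.random.default_rng(10), n_generations=5, n_sires=4, n_dams=20
        )
        assert final.tbv.mean() > pop.tbv.mean()


def test_allele_frequency_drift_martingale():
    """Mean allele-frequency change under random mating is ~0 over replicates."""
    genome = GenomeMap(n_chromosomes=1, chrom_length_bp=1_000_000)
    fh = make_founders(genome, n_hap=30, sites_per_chrom=30, seed=20)
    arch = build_architecture(fh, 10, seed=21)
    changes = []
    for rep in range(60):
        pop = make_population(arch, n=30, generation=-2, seed=300 + rep)
        p0 = pop.allele1_frequency()
        final = run_historical(
            pop, genome, arch, np.random.default_rng(400 + rep),
            n_generations=2, n_sires=3, n_dams=15, select=False,
        )
        changes.append(final.allele1_frequency() - p0)
    mean_change = np.concatenate(changes).mean()
    assert abs(mean_change) < 0.01
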