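"""Simulator: epistasis algebra, mutation law, cycle engine, selection oracle."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_cycle_composition, two_type_chain

from mtdrift.evosim import (
    CellState,
    EffectTable,
    Population,
    SimConfig,
    apply_mutation_effect,
    draw_mutations,
    run_cycle,
    run_experiment,
    summarize_trajectory,
)

FS = 308.0 / 60.0   # founder stressed doubling time, hours
FN = 93.0 / 60.0    # founder unstressed doubling time (the floor)


class TestEpistasis:
    def test_neutral_mutation_is_identity(self):
        for d_g in (FS, 3.0, FN):
            assert apply_mutation_effect(d_g, 0.0, FS, FN) == pytest.approx(d_g)

    def test_floor_reaching_mutation(self):
        d_r = np.log2(FN / FS)   # mutation alone reaches the floor: k = 0
        assert apply_mutation_effect(4.0, d_r, FS, FN) == pytest.approx(FN)
        # even stronger effects stay floored
        assert apply_mutation_effect(4.0, d_r - 1.0, FS, FN) == pytest.approx(FN)

    def test_sequential_factors_multiply(self):
        """Remaining gap after two mutations is k1*k2 times the initial gap."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            d_r1, d_r2 = rng.uniform(-0.3, 0.2, 2)
            d0 = rng.uniform(FN, 8.0)
            k = lambda dr: max((2.0 ** dr * FS - FN) / (FS - FN), 0.0)
            sequential = apply_mutation_effect(
                apply_mutation_effect(d0, d_r1, FS, FN), d_r2, FS, FN)
            closed_form = FN + k(d_r1) * k(d_r2) * (d0 - FN)
            assert sequential == pytest.approx(closed_form, rel=1e-12)

    def test_absolute_mode_agrees_with_log2_mode(self):
        d_r_log2 = -0.2
        d_abs = 2.0 ** d_r_log2 * FS
        a = apply_mutation_effect(4.0, d_r_log2, FS, FN, mode="log2")
        b = apply_mutation_effect(4.0, d_abs, FS, FN, mode="absolute")
        assert a == pytest.approx(b)

    def test_degenerate_founders_refused(self):
        with pytest.raises(ValueError):
            apply_mutation_effect(2.0, 0.0, FN, FN)


class TestDrawMutations:
    def test_zero_rates_always_empty(self, effect_table):
        rng = np.random.default_rng(0)
        cell = CellState(division_time_h=FS)
        for _ in range(200):
            assert draw_mutations(rng, 0.0, 0.0, 12_000_000, effect_table, cell) == []

    def test_poisson_mean_of_point_mutations(self, effect_table):
        """Printed rates give 3.96e-3 point mutations per division; the
        per-division draw must match that mean by Monte Carlo."""
        from mtdrift.evosim import _EffectModel

        cfg = SimConfig(n=10, m_t=1.0, n_cycles=1)
        assert cfg.mu_snp * cfg.genome_bp == pytest.approx(3.96e-3)
        model = _EffectModel(effect_table, cfg)
        rng = np.random.default_rng(123)
        n_draws = 200_000
        total = 0
        for _ in range(n_draws):
            cell = CellState(division_time_h=FS)
            events = draw_mutations(rng, cfg.mu_snp, cfg.mu_dup, cfg.genome_bp,
                                    effect_table, cell, config=cfg, _model=model)
            total += sum(1 for e in events if e.kind == "point")
        rate = total / n_draws
        se = np.sqrt(3.96e-3 / n_draws)
        assert abs(rate - 3.96e-3) < 3 * se

    def test_fully_duplicated_cell_gets_no_duplication(self, effect_table):
        rng = np.random.default_rng(1)
        chroms = set(effect_table.chroms.chrom)
        cell = CellState(duplicated_chroms=set(chroms), division_time_h=FS)
        events = draw_mutations(rng, 0.0, 1.0, 12_000_000, effect_table, cell)
        assert all(e.kind != "duplication" for e in events)
        assert cell.duplicated_chroms == chroms

    def test_effectual_hit_changes_division_time(self, effect_table):
        rng = np.random.default_rng(2)
        cell = CellState(division_time_h=FS)
        # force a point mutation every division by inflating the rate
        for _ in range(50):
            draw_mutations(rng, 1e-7, 0.0, 12_000_000, effect_table, cell)
        assert len(cell.mutated_genes) > 0


class TestRunCycle:
    def zero_rate_config(self, n, m_t, **kw):
        kw.setdefault("max_divisions", 100)
        return SimConfig(n=n, m_t=m_t, n_cycles=1, mu_dup=0.0, mu_snp=0.0,
                         n_replicates=1, **kw)

    def test_cap_arithmetic(self, effect_table):
        cfg = self.zero_rate_config(4, 2.0)
        pop = Population.founders(4, cfg)
        rng = np.random.default_rng(0)
        new_pop, info = run_cycle(pop, 2.0, rng, cfg, effect_table)
        assert info["final_size"] == 16 and info["capped"]
        assert new_pop.size == 4

    def test_homogeneous_population_unchanged(self, effect_table):
        cfg = self.zero_rate_config(50, 4.0)
        pop = Population.founders(50, cfg)
        rng = np.random.default_rng(1)
        new_pop, _ = run_cycle(pop, 4.0, rng, cfg, effect_table)
        assert new_pop.mean_division_time() == pytest.approx(FS)
        assert set(g for g, _, _ in new_pop.cohorts) == {0}

    def test_fast_subclone_enriched_at_cap(self, effect_table):
        """Two subclones (1 h vs 2 h): after a long cycle the fast clone's
        cap frequency exceeds its founding frequency, consistent with the
        deterministic growth ratio."""
        cells = ([CellState(division_time_h=1.0)] * 4
                 + [CellState(division_time_h=2.0)] * 4)
        pop = Population.from_cells(cells)
        cfg = self.zero_rate_config(8, 6.0)
        fast_expected, slow_expected = brute_force_cycle_composition(4, 4, 1.0, 2.0, 6.0)
        rng = np.random.default_rng(2)
        new_pop, info = run_cycle(pop, 6.0, rng, cfg, effect_table)
        fast_gid = next(g.gid for g in new_pop.genotypes.values()
                        if g.division_time_h == 1.0)
        fast_n = sum(c for g, _, c in new_pop.cohorts if g == fast_gid)
        assert fast_expected / (fast_expected + slow_expected) > 0.5
        # survivors are a hypergeometric sample around the deterministic frequency
        assert fast_n / 8 > 0.5

    def test_all_cells_at_max_age_cannot_expand(self, effect_table):
        cfg = SimConfig(n=6, m_t=2.0, n_cycles=1, mu_dup=0, mu_snp=0,
                        max_divisions=3, n_replicates=1)
        cells = [CellState(division_time_h=FS, divisions_used=3) for _ in range(6)]
        pop = Population.from_cells(cells)
        new_pop, info = run_cycle(pop, 2.0, np.random.default_rng(0), cfg, effect_table)
        assert not info["capped"]
        assert info["final_size"] == 6
        assert new_pop.size == 6

    def test_replicative_age_limit_respected(self, effect_table):
        cfg = self.zero_rate_config(4, 5.0, max_divisions=2)
        pop = Population.founders(4, cfg)
        new_pop, info = run_cycle(pop, 5.0, np.random.default_rng(3), cfg, effect_table)
        assert all(age <= 2 for _, age, _ in new_pop.cohorts)


class TestSelectionOracle:
    def test_fixation_statistics_match_enumeration(self, effect_table):
        """Two-type serial-bottleneck process at N=4: fixation probability
        and conditional sweep time agree with the exact Markov-chain
        enumeration within Monte-Carlo error.  The fractional M_t makes
        the cap composition asymmetric (18 cells, 10 fast from an even
        start), so fixation probability is informative (~0.78) rather
        than pinned at 0.5 or ~1 by wave synchrony."""
        n, m_t, d_fast, d_slow = 4, 2.2, 1.0, 1.3
        p_fix, t_cond = two_type_chain(n, d_fast, d_slow, m_t)
        cfg = SimConfig(n=n, m_t=m_t, n_cycles=1, mu_dup=0, mu_snp=0,
                        max_divisions=1000, n_replicates=1)
        n_rep = 600
        rng = np.random.default_rng(2024)
        fixed_fast = 0
        fix_cycles = []
        for _ in range(n_rep):
            cells = ([CellState(division_time_h=d_fast)] * 2
                     + [CellState(division_time_h=d_slow)] * 2)
            pop = Population.from_cells(cells)
            for cycle in range(1, 200):
                pop, _ = run_cycle(pop, m_t, rng, cfg, effect_table)
                times = {pop.genotypes[g].division_time_h for g, _, _ in pop.cohorts}
                if times == {d_fast}:
                    fixed_fast += 1
                    fix_cycles.append(cycle)
                    break
                if times == {d_slow}:
                    break
        p_hat = fixed_fast / n_rep
        se_p = np.sqrt(p_fix[2] * (1 - p_fix[2]) / n_rep)
        assert abs(p_hat - p_fix[2]) < 3 * se_p
        t_hat = np.mean(fix_cycles)
        se_t = np.std(fix_cycles, ddof=1) / np.sqrt(len(fix_cycles))
        assert abs(t_hat - t_cond[2]) < 3 * se_t


class TestExperiment:
    def neutral_table(self):
        """All effects exactly neutral (D_r = 0 everywhere)."""
        genes = pd.DataFrame({
            "gene": [f"G{i}" for i in range(100)],
            "d_nostress_h": FN, "d_stress_h": FS,
            "effectual_sites": 300,
        })
        chroms = pd.DataFrame({
            "chrom": [f"chr{r}" for r in
                      "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI".split()],
            "d_nostress_h": FN, "d_stress_h": FS,
        })
        return EffectTable(genes=genes, chroms=chroms)

    def test_zero_rates_flat_trajectory(self, effect_table):
        cfg = SimConfig(n=100, m_t=4, n_cycles=5, mu_dup=0, mu_snp=0,
                        n_replicates=3, seed=9)
        res = run_experiment(cfg, effect_table)
        assert np.allclose(res.trajectory.mean_d_h, FS, rtol=0, atol=1e-12)

    def test_neutral_mutations_leave_mean_constant(self):
        """With every D_r = 0 the mean division time cannot drift at all:
        k = 1 mutations are exact identities."""
        cfg = SimConfig(n=300, m_t=5, n_cycles=10, n_replicates=4, seed=5,
                        mu_snp=1e-8)   # elevated rate to exercise bookkeeping
        res = run_experiment(cfg, self.neutral_table())
        assert np.allclose(res.trajectory.mean_d_h, FS)
        assert not res.mutations.empty   # mutations did occur, all neutral

    def test_floor_never_violated(self):
        """Strongly beneficial table at high rates: no genotype below the floor."""
        genes = pd.DataFrame({
            "gene": [f"G{i}" for i in range(50)],
            "d_nostress_h": FN,
            "d_stress_h": FN * 1.001,    # nearly floor-reaching deletions
            "effectual_sites": 100_000,
        })
        chroms = pd.DataFrame({"chrom": ["chrI", "chrII"],
                               "d_nostress_h": FN, "d_stress_h": FN})
        table = EffectTable(genes=genes, chroms=chroms)
        cfg = SimConfig(n=100, m_t=4, n_cycles=6, mu_snp=1e-7, mu_dup=1e-3,
                        n_replicates=2, seed=13)
        res = run_experiment(cfg, table)
        # audit every genotype created across the run via the final populations
        assert (res.trajectory.mean_d_h >= FN - 1e-12).all()

    def test_lineage_mutation_bookkeeping(self, effect_table):
        """No gene or chromosome is ever mutated twice along any lineage."""
        cfg = SimConfig(n=50, m_t=4, n_cycles=4, mu_snp=1e-7, mu_dup=1e-2,
                        n_replicates=1, seed=21)
        table = effect_table
        rng = np.random.default_rng(17)
        pop = Population.founders(cfg.n, cfg)
        for _ in range(cfg.n_cycles):
            pop, _ = run_cycle(pop, 4.0, rng, cfg, table)
        for g in pop.genotypes.values():
            if g.parent is None:
                continue
            parent = pop.genotypes[g.parent]
            assert parent.mutated_genes <= g.mutated_genes
            assert parent.duplicated_chroms <= g.duplicated_chroms
            # frozensets guarantee uniqueness; check growth is by new targets only
            assert g.mutated_genes - parent.mutated_genes == \
                g.mutated_genes.difference(parent.mutated_genes)

    def test_seed_reproducibility(self, effect_table):
        cfg = SimConfig(n=200, m_t=4, n_cycles=3, n_replicates=2, seed=77)
        a = run_experiment(cfg, effect_table)
        b = run_experiment(cfg, effect_table)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)
        pd.testing.assert_frame_equal(a.mutations, b.mutations)


class TestSummaries:
    def test_flat_trajectory_zero_reduction(self, effect_table):
        cfg = SimConfig(n=50, m_t=3, n_cycles=3, mu_dup=0, mu_snp=0,
                        n_replicates=2, seed=1)
        res = run_experiment(cfg, effect_table)
        summ = summarize_trajectory(res)
        assert np.allclose(summ.log2_fold_reduction, 0.0)
        assert np.allclose(summ.percent_of_max, 0.0)

    def test_single_replicate_sem_missing(self, effect_table):
        cfg = SimConfig(n=50, m_t=3, n_cycles=2, mu_dup=0, mu_snp=0,
                        n_replicates=1, seed=1)
        summ = summarize_trajectory(run_experiment(cfg, effect_table))
        assert summ.sem_d_h.isna().all()

    def test_halving_gives_unit_log2_reduction(self, effect_table):
        cfg = SimConfig(n=10, m_t=2, n_cycles=2, n_replicates=1, seed=0)
        res = run_experiment(cfg, effect_table)
        res.trajectory.loc[res.trajectory.cycle > 0, "mean_d_h"] = FS / 2
        summ = summarize_trajectory(res)
        assert summ.loc[summ.cycle > 0, "log2_fold_reduction"].iloc[0] == \
            pytest.approx(1.0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n=0),
        dict(mu_dup=-1e-5),
        dict(d_founder_stress_h=1.0, d_founder_nostress_h=1.5),
        dict(m_t=-2.0),
        dict(epistasis_mode="linear"),
    ])
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_m_t_schedule_broadcast(self):
        cfg = SimConfig(m_t=4.8, n_cycles=50)
        assert cfg.m_t_schedule().sum() == pytest.approx(240.0)
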