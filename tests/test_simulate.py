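"""Tests of the individual-based forward simulator."""

import math

import numpy as np
import pandas as pd
import pytest

from maternalqg import (
    GeneticArchitecture,
    SelectionRegime,
    SimulationConfig,
    SimulationError,
    init_founders,
    predict_response,
    reproduce,
    run,
    select,
    simulate_pedigree,
)

NEUTRAL = SelectionRegime(0.0, 0.0)


def make_config(**kw):
    defaults = dict(
        arch=GeneticArchitecture(1, 1, 0.5, 1, 1),
        sel=NEUTRAL,
        seed=1234,
        n_per_generation=400,
        n_generations=5,
        burn_in=0,
        response_window=(1, 5),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestFounders:
    def test_zero_variance_config_gives_zero_population(self):
        cfg = make_config(arch=GeneticArchitecture(0, 0, 0, 0, 0))
        pop = init_founders(cfg, np.random.default_rng(0))
        for arr in (pop.a_o, pop.a_dee, pop.e_o, pop.e_dee, pop.z_o, pop.z_dee):
            np.testing.assert_array_equal(arr, 0.0)

    def test_founder_genetic_covariance_matches_configuration(self):
        cfg = make_config(
            arch=GeneticArchitecture(1, 1, 0.5), n_per_generation=100_000
        )
        pop = init_founders(cfg, np.random.default_rng(5))
        emp = np.cov(pop.a_o, pop.a_dee, ddof=1)
        se = math.sqrt((1 * 1 + 0.5**2) / pop.size)
        assert emp[0, 1] == pytest.approx(0.5, abs=3 * se)
        assert emp[0, 0] == pytest.approx(1.0, abs=3 * math.sqrt(2 / pop.size))

    def test_founder_maternal_input_carries_stationary_cross_covariance(self):
        """Founders' maternal environment covaries with own breeding values
        exactly as a real dam's phenotype would: Cov(m, a_o) = C/2."""
        arch = GeneticArchitecture(1, 1, 0.8, 0, 0)
        cfg = make_config(arch=arch, n_per_generation=100_000)
        pop = init_founders(cfg, np.random.default_rng(9))
        m = pop.z_o - pop.a_o - pop.e_o
        se = math.sqrt((arch.var_zo * arch.var_zdee) / pop.size)
        assert np.cov(m, pop.a_o, ddof=1)[0, 1] == pytest.approx(0.4, abs=3 * se)

    def test_sexes_are_balanced(self):
        pop = init_founders(make_config(), np.random.default_rng(2))
        assert pop.females.size == pop.males.size == pop.size // 2


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_trajectories(self):
        cfg = make_config(sel=SelectionRegime(0.1, 0.05), n_replicates=2)
        r1, r2 = run(cfg), run(cfg)
        for t1, t2 in zip(r1.trajectories, r2.trajectories):
            pd.testing.assert_frame_equal(t1, t2)

    def test_identical_seed_gives_bit_identical_pedigrees(self):
        arch = GeneticArchitecture(1, 1, 0.5, 1, 1)
        p1 = simulate_pedigree(arch, 200, seed=77)
        p2 = simulate_pedigree(arch, 200, seed=77)
        pd.testing.assert_frame_equal(p1, p2)


class TestSelection:
    def test_neutral_selection_gives_uniform_fitness_and_zero_gradients(self):
        pop = init_founders(make_config(), np.random.default_rng(3))
        stats = select(pop, NEUTRAL, make_config())
        np.testing.assert_array_equal(pop.fitness, 1.0)
        assert stats.realized_beta_o == pytest.approx(0.0, abs=1e-12)
        assert stats.frac_clamped == 0.0

    def test_realized_gradients_equal_nominal_coefficients(self):
        """Linear fitness on centered phenotypes makes the measured
        Lande-Arnold gradients equal the nominal betas (no clamping)."""
        cfg = make_config(n_per_generation=50_000)
        pop = init_founders(cfg, np.random.default_rng(4))
        sel = SelectionRegime(beta_o=0.05, beta_dee=0.02)
        stats = select(pop, sel, cfg)
        assert stats.frac_clamped == 0.0
        assert stats.realized_beta_o == pytest.approx(0.05, abs=1e-10)
        assert stats.realized_beta_dee == pytest.approx(0.02, abs=1e-10)

    def test_selected_dam_mean_shift_matches_selection_differential(self):
        """Fitness-proportional sampling realizes S = cov(w, z)/mean(w)."""
        cfg = make_config(n_per_generation=40_000, offspring_per_pair=2)
        rng = np.random.default_rng(11)
        pop = init_founders(cfg, rng)
        sel = SelectionRegime(beta_o=0.2, beta_dee=0.0)
        select(pop, sel, cfg)
        child = reproduce(pop, cfg, rng, start_id=pop.size + 1)
        dam_z = pop.z_o[np.searchsorted(pop.id, child.dam_id)]
        expected = 0.2 * pop.z_o.var(ddof=1)  # var(z_o) > 1: maternal path
        se = math.sqrt(pop.z_o.var(ddof=1) / np.unique(child.dam_id).size)
        assert dam_z.mean() - pop.z_o.mean() == pytest.approx(expected, abs=3 * se)

    def test_clamping_reported_and_fitness_nonnegative(self):
        cfg = make_config(n_per_generation=10_000)
        pop = init_founders(cfg, np.random.default_rng(6))
        stats = select(pop, SelectionRegime(beta_o=2.0), cfg)
        assert stats.frac_clamped > 0
        assert (pop.fitness >= 0).all()

    def test_all_zero_fitness_raises_with_generation_context(self):
        cfg = make_config()
        pop = init_founders(cfg, np.random.default_rng(7))
        pop.fitness = np.zeros(pop.size)
        with pytest.raises(SimulationError, match="fitness"):
            reproduce(pop, cfg, np.random.default_rng(8), start_id=1000)


class TestReproduction:
    def test_unidirectional_no_write_back_to_parents(self):
        """Offspring receive the dam's z_dee; nothing flows back."""
        cfg = make_config()
        rng = np.random.default_rng(12)
        pop = init_founders(cfg, rng)
        before = {k: getattr(pop, k).copy() for k in ("a_o", "a_dee", "z_o", "z_dee")}
        select(pop, NEUTRAL, cfg)
        child = reproduce(pop, cfg, rng, start_id=pop.size + 1)
        for k, arr in before.items():
            np.testing.assert_array_equal(arr, getattr(pop, k))
        dam_pos = np.searchsorted(pop.id, child.dam_id)
        np.testing.assert_allclose(
            child.z_o, child.a_o + child.e_o + pop.z_dee[dam_pos]
        )
        np.testing.assert_allclose(child.z_dee, child.a_dee + child.e_dee)

    def test_deterministic_phenotypes_when_all_variances_zero(self):
        cfg = make_config(arch=GeneticArchitecture(0, 0, 0, 0, 0))
        rng = np.random.default_rng(13)
        pop = init_founders(cfg, rng)
        select(pop, NEUTRAL, cfg)
        child = reproduce(pop, cfg, rng, start_id=pop.size + 1)
        np.testing.assert_array_equal(child.z_o, 0.0)
        np.testing.assert_array_equal(child.z_dee, 0.0)

    def test_dam_offspring_breeding_value_regression_is_half(self):
        """Diploid transmission: slope of offspring a_dee on dam a_dee = 0.5."""
        arch = GeneticArchitecture(1, 1, 0, 1, 1)
        ped = simulate_pedigree(arch, n_families=5000, seed=42, offspring_per_pair=1)
        dams = ped.set_index("id")["a_dee"]
        off = ped[ped.dam_id > 0]
        x = dams.loc[off.dam_id].to_numpy()
        y = off["a_dee"].to_numpy()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        resid = y - y.mean() - slope * (x - x.mean())
        se = np.sqrt(resid.var(ddof=2) / (x.size * x.var(ddof=1)))
        assert slope == pytest.approx(0.5, abs=3 * se)

    def test_neutral_additive_variance_is_stationary(self):
        arch = GeneticArchitecture(1.0, 0.5, 0.25, 1, 1)
        cfg = make_config(arch=arch, n_per_generation=20_000, n_generations=1,
                          response_window=(1, 1))
        res = run(cfg)
        last = res.trajectories[0].iloc[-1]
        n = cfg.n_per_generation
        assert last["var_a_o"] == pytest.approx(1.0, abs=3 * math.sqrt(2 / n))
        assert last["var_a_dee"] == pytest.approx(0.5, abs=3 * 0.5 * math.sqrt(2 / n))


class TestRun:
    def test_neutral_run_shows_no_trend(self):
        cfg = make_config(
            n_per_generation=1000, n_generations=20, n_replicates=40,
            response_window=(1, 20), seed=999,
        )
        res = run(cfg)
        assert abs(res.response_zo_mean) < 3 * res.response_zo_se
        assert abs(res.response_zdee_mean) < 3 * res.response_zdee_se

    def test_response_without_direct_genetic_variance(self):
        """Selection on growth still works through heritable maternal care."""
        arch = GeneticArchitecture(v_ao=0, v_adee=1, cov_a=0, v_eo=1, v_edee=1)
        cfg = SimulationConfig(
            arch=arch, sel=SelectionRegime(beta_o=0.1), seed=321,
            n_per_generation=1000, n_generations=20, n_replicates=40,
            burn_in=3, response_window=(5, 20),
        )
        res = run(cfg)
        expected = predict_response(arch, cfg.sel).delta_zo  # 0.05
        assert res.response_zo_mean > 3 * res.response_zo_se
        assert res.response_zo_mean == pytest.approx(expected, abs=3 * res.response_zo_se)

    def test_transient_overshoot_under_maternal_selection(self):
        """Selecting mothers on DEE shifts the offspring environment by the
        full phenotypic covariance once; afterwards only half the additive
        variance flows per generation. The generation-1 growth response
        therefore overshoots the asymptotic rate by beta_dee*(V_A(DEE)/2 +
        V_E(DEE))."""
        arch = GeneticArchitecture(v_ao=1, v_adee=1, cov_a=0, v_eo=1, v_edee=1)
        sel = SelectionRegime(beta_o=0.0, beta_dee=0.4)
        cfg = SimulationConfig(
            arch=arch, sel=sel, seed=555, n_per_generation=800,
            n_generations=15, n_replicates=60, burn_in=3, response_window=(5, 15),
        )
        res = run(cfg)
        first = np.array(
            [t["delta_z_o"].iloc[cfg.burn_in + 1] for t in res.trajectories]
        )
        se1 = first.std(ddof=1) / math.sqrt(first.size)
        asymptotic = predict_response(arch, sel).delta_zo  # 0.2
        overshoot = sel.beta_dee * (0.5 * arch.v_adee + arch.v_edee)  # 0.6
        assert first.mean() - asymptotic > 5 * se1
        assert first.mean() == pytest.approx(asymptotic + overshoot, abs=3 * se1)
        # and the windowed rate settles back to the analytic value
        assert res.response_zo_mean == pytest.approx(
            asymptotic, abs=3 * res.response_zo_se
        )

    def test_bulmer_deficit_with_constant_segregation_variance(self):
        """The textbook fixed-G0/2 scheme builds negative disequilibrium:
        additive variance drops below its founder value under selection."""
        arch = GeneticArchitecture(1, 0, 0, 0.2, 0)
        cfg = SimulationConfig(
            arch=arch, sel=SelectionRegime(beta_o=0.5), seed=17,
            n_per_generation=4000, n_generations=10, n_replicates=20,
            burn_in=0, response_window=(1, 10), segregation_variance="constant",
        )
        res = run(cfg)
        late = np.array([t["var_a_o"].iloc[-1] for t in res.trajectories])
        se = late.std(ddof=1) / math.sqrt(late.size)
        assert late.mean() < 1.0 - 3 * se

    def test_window_validation(self):
        with pytest.raises(ValueError, match="response_window"):
            make_config(response_window=(1, 50))


class TestPedigreeOutput:
    def test_tsv_contract_columns_and_parent_links(self, neutral_pedigree):
        from maternalqg.simulate import PEDIGREE_COLUMNS

        assert tuple(neutral_pedigree.columns) == PEDIGREE_COLUMNS
        founders = neutral_pedigree[neutral_pedigree.generation == 0]
        off = neutral_pedigree[neutral_pedigree.generation == 1]
        assert (founders.dam_id == 0).all() and (founders.sire_id == 0).all()
        assert off.dam_id.isin(founders.id).all()
        assert off.sire_id.isin(founders.id).all()
        assert set(neutral_pedigree.sex) == {"F", "M"}
        # monogamous neutral design: each dam pairs with exactly one sire
        assert (off.groupby("dam_id")["sire_id"].nunique() == 1).all()
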