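"""Stochastic engine: propensity conventions, exactness, ensemble statistics."""

import numpy as np
import pytest

from chondrosim import (
    ensemble_summary,
    propensities,
    run_ensemble,
    simulate_ode,
    simulate_ssa,
)

from conftest import small_model


class TestPropensities:
    def test_bimolecular_heterodimer(self):
        m = small_model(
            species=[("A", 3, "protein"), ("B", 4, "protein"), ("C", 0, "protein")],
            reactions=[("bind", {"A": 1, "B": 1}, {"C": 1}, (), "k")],
            parameters=[("k", 0.5, "per_molecule_per_second")],
        )
        assert propensities(m, [3, 4, 0])[0] == pytest.approx(6.0)

    def test_homodimer_uses_combinatorial_count(self):
        """2A -> B with A=5, k=1 has propensity C(5,2) = 10."""
        m = small_model(
            species=[("A", 5, "protein"), ("B", 0, "protein")],
            reactions=[("dim", {"A": 2}, {"B": 1}, (), "k")],
            parameters=[("k", 1.0, "per_molecule_per_second")],
        )
        assert propensities(m, [5, 0])[0] == pytest.approx(10.0)
        assert propensities(m, [1, 0])[0] == 0.0

    def test_zero_count_reactant_gives_zero(self):
        m = small_model(
            species=[("A", 0, "protein"), ("B", 9, "protein")],
            reactions=[("bind", {"A": 1, "B": 1}, {}, (), "k")],
            parameters=[("k", 2.0, "per_molecule_per_second")],
        )
        assert propensities(m, [0, 9])[0] == 0.0

    def test_modifier_multiplies_count(self):
        m = small_model(
            species=[("A", 7, "protein"), ("E", 3, "enzyme"), ("B", 0, "protein")],
            reactions=[("cat", {"A": 1}, {"B": 1}, ("E",), "k")],
            parameters=[("k", 0.1, "per_molecule_per_second")],
        )
        assert propensities(m, [7, 3, 0])[0] == pytest.approx(2.1)

    def test_negative_state_is_rejected(self, model):
        with pytest.raises(ValueError):
            propensities(model, -np.ones(len(model.species)))


class TestSimulateSSA:
    def test_no_reactions_means_constant_trajectory(self):
        from chondrosim.network import COMPARTMENTS, ModelSpec, SpeciesDef

        m = ModelSpec("c", "1", COMPARTMENTS,
                      [SpeciesDef("A", "A", "cytoplasm", 17, "protein")], [], [])
        for seed in (0, 1, 99):
            tc = simulate_ssa(m, horizon_h=10.0, seed=seed,
                              grid_h=np.array([0.0, 5.0, 10.0]))
            assert np.all(tc["A"] == 17)

    def test_same_seed_is_bit_identical(self, birth_death):
        m = birth_death()
        a = simulate_ssa(m, horizon_h=24.0, seed=11)
        b = simulate_ssa(m, horizon_h=24.0, seed=11)
        assert np.array_equal(a.values, b.values)
        c = simulate_ssa(m, horizon_h=24.0, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_birth_death_stationary_mean(self, birth_death):
        """Stationary distribution is Poisson(lam/mu): mean within 3 SE."""
        lam, mu = 5.0, 0.01
        m = birth_death(lam, mu)
        ens = run_ensemble(m, horizon_h=48.0, n_runs=100, base_seed=100,
                           grid_h=np.array([0.0, 24.0, 48.0]))
        final = ens.stack("A")[:, -1]
        expected = lam / mu
        se = np.sqrt(expected / 100)
        assert abs(final.mean() - expected) < 3 * se

    def test_pure_death_binomial_thinning(self):
        """A(0)=1000, half-life 30 h: mean at 30 h is 500 +- 3*sqrt(250)."""
        k = np.log(2) / (30 * 3600)
        m = small_model(
            species=[("A", 1000, "protein")],
            reactions=[("death", {"A": 1}, {}, (), "k")],
            parameters=[("k", k, "per_second")],
        )
        ens = run_ensemble(m, horizon_h=30.0, n_runs=100, base_seed=7,
                           grid_h=np.array([0.0, 30.0]))
        final = ens.stack("A")[:, -1]
        se = np.sqrt(1000 * 0.5 * 0.5 / 100)
        assert abs(final.mean() - 500.0) < 3 * np.sqrt(250) / np.sqrt(100) + 3 * se


class TestEnsembles:
    def test_single_run_equals_simulate_ssa_with_base_seed(self, birth_death):
        m = birth_death()
        grid = np.array([0.0, 10.0, 20.0])
        ens = run_ensemble(m, horizon_h=20.0, n_runs=1, base_seed=5, grid_h=grid)
        solo = simulate_ssa(m, horizon_h=20.0, seed=5, grid_h=grid)
        assert np.array_equal(ens.trajectories[0].values, solo.values)

    def test_identical_constant_trajectories_have_zero_variance(self):
        from chondrosim.network import COMPARTMENTS, ModelSpec, SpeciesDef

        m = ModelSpec("c", "1", COMPARTMENTS,
                      [SpeciesDef("A", "A", "cytoplasm", 9, "protein")], [], [])
        ens = run_ensemble(m, horizon_h=5.0, n_runs=5, base_seed=0,
                           grid_h=np.array([0.0, 5.0]))
        summ = ensemble_summary(ens)
        assert np.all(summ.variance == 0.0)
        assert np.all(summ.mean == 9.0)

    def test_birth_death_variance_matches_poisson(self, birth_death):
        """Stationary Poisson: variance approximately equals the mean."""
        m = birth_death(2.0, 0.01)
        ens = run_ensemble(m, horizon_h=48.0, n_runs=200, base_seed=300,
                           grid_h=np.array([0.0, 48.0]))
        final = ens.stack("A")[:, -1]
        mean, var = final.mean(), final.var(ddof=1)
        # var/mean ~ 1 with sampling error ~ sqrt(2/(n-1)) ~ 0.1
        assert abs(var / mean - 1.0) < 0.35

    def test_variance_requires_two_runs(self, birth_death):
        ens = run_ensemble(birth_death(), horizon_h=1.0, n_runs=1, base_seed=0,
                           grid_h=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            ensemble_summary(ens)

    def test_cv_flagged_nan_where_mean_zero(self, birth_death):
        m = birth_death(0.0, 0.01, a0=0)  # nothing ever happens
        ens = run_ensemble(m, horizon_h=1.0, n_runs=3, base_seed=0,
                           grid_h=np.array([0.0, 1.0]))
        summ = ensemble_summary(ens)
        assert np.all(np.isnan(summ.cv))

    def test_seeds_are_distinct_and_order_independent(self, birth_death):
        m = birth_death()
        grid = np.array([0.0, 24.0])
        ens = run_ensemble(m, horizon_h=24.0, n_runs=4, base_seed=10, grid_h=grid)
        assert ens.seeds == [10, 11, 12, 13]
        # independence: each trajectory matches a solo run with its own seed
        for seed, tc in zip(ens.seeds, ens.trajectories):
            solo = simulate_ssa(m, horizon_h=24.0, seed=seed, grid_h=grid)
            assert np.array_equal(tc.values, solo.values)


class TestAgainstODE:
    def test_ssa_mean_matches_ode_for_linear_network(self, linear_chain):
        """First-order networks: the SSA mean obeys the rate equations, so
        100 runs must agree with the ODE within 3 standard errors."""
        grid = np.array([0.0, 12.0, 24.0])
        n = 100
        ens = run_ensemble(linear_chain, horizon_h=24.0, n_runs=n, base_seed=50,
                           grid_h=grid)
        ode = simulate_ode(linear_chain, horizon_h=24.0, grid_h=grid)
        for sid in ("A", "B"):
            samples = ens.stack(sid)[:, -1]
            se = samples.std(ddof=1) / np.sqrt(n)
            assert abs(samples.mean() - ode[sid][-1]) < 3 * se

    def test_full_model_ensemble_mmp1_varies_between_runs(self, model):
        """Under IL-1+OSM the stochastic runs disagree on the size and timing
        of maximal MMP-1 induction."""
        from chondrosim import make_treatment

        sc = make_treatment(model, True, True, False)
        grid = np.arange(0.0, 48.0 + 1e-9, 1.0)
        ens = run_ensemble(model, sc, horizon_h=48.0, n_runs=8, base_seed=1,
                           grid_h=grid)
        peaks = ens.stack("mRNA_MMP1").max(axis=1)
        times = grid[np.argmax(ens.stack("mRNA_MMP1"), axis=1)]
        assert peaks.std(ddof=1) > 0
        assert times.std(ddof=1) > 0
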