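"""Deterministic engine: mass-action semantics, integration, readouts."""

import numpy as np
import pytest

from chondrosim import build_rate_function, peak_metrics, percent_release, simulate_ode
from chondrosim.network import COMPARTMENTS, ModelSpec, RateParameter, ReactionDef, SpeciesDef
from chondrosim.ode import TimeCourse, conservation_drift

from conftest import small_model


class TestRateFunction:
    def test_single_reaction_mass_action(self):
        """A ->(k) B with A=10, k=0.1 gives dA/dt=-1, dB/dt=+1."""
        m = small_model(
            species=[("A", 10, "protein"), ("B", 0, "protein")],
            reactions=[("conv", {"A": 1}, {"B": 1}, (), "k")],
            parameters=[("k", 0.1, "per_second")],
        )
        f = build_rate_function(m)
        assert np.allclose(f(np.array([10.0, 0.0])), [-1.0, 1.0])

    def test_zero_state_gives_zero_flux(self):
        m = small_model(
            species=[("A", 0, "protein"), ("B", 0, "protein")],
            reactions=[("conv", {"A": 1}, {"B": 1}, (), "k"),
                       ("bind", {"A": 1, "B": 1}, {}, (), "k")],
            parameters=[("k", 0.5, "per_second")],
        )
        f = build_rate_function(m)
        assert np.allclose(f(np.zeros(2)), 0.0)

    def test_random_network_matches_analytic_flux_oracle(self):
        """Evaluator output equals an independently assembled flux formula on
        a random 5-species network."""
        rng = np.random.default_rng(7)
        n_s, n_r = 5, 8
        species = [(f"S{i}", 0, "protein") for i in range(n_s)]
        reactions, parameters = [], []
        spec_list = []
        for j in range(n_r):
            reactants = {f"S{rng.integers(n_s)}": int(rng.integers(1, 3))}
            products = {f"S{rng.integers(n_s)}": 1}
            modifiers = tuple({f"S{rng.integers(n_s)}"} - set(reactants))
            reactions.append((f"r{j}", reactants, products, modifiers, f"k{j}"))
            parameters.append((f"k{j}", float(rng.uniform(0.1, 2.0)), "per_second"))
            spec_list.append((reactants, products, modifiers))
        m = small_model(species, reactions, parameters)
        state = rng.uniform(0.5, 20.0, n_s)
        idx = {f"S{i}": i for i in range(n_s)}

        expected = np.zeros(n_s)
        for (reactants, products, modifiers), (_, kval, _) in zip(spec_list, parameters):
            flux = kval
            for sid, sto in reactants.items():
                flux *= state[idx[sid]] ** sto
            for sid in modifiers:
                flux *= state[idx[sid]]
            for sid, sto in reactants.items():
                expected[idx[sid]] -= sto * flux
            for sid, sto in products.items():
                expected[idx[sid]] += sto * flux

        f = build_rate_function(m)
        assert np.allclose(f(state), expected, rtol=1e-12)


class TestSimulateODE:
    def test_empty_reaction_set_is_constant(self):
        m = ModelSpec("empty", "1", COMPARTMENTS,
                      [SpeciesDef("A", "A", "cytoplasm", 42, "protein")], [], [])
        tc = simulate_ode(m, horizon_h=48.0)
        assert np.all(tc["A"] == 42.0)

    def test_pure_decay_matches_closed_form_half_life(self):
        half_life_h = 30.0
        k = np.log(2) / (half_life_h * 3600)
        m = small_model(
            species=[("A", 1000, "protein")],
            reactions=[("deg", {"A": 1}, {}, (), "k")],
            parameters=[("k", k, "per_second")],
        )
        tc = simulate_ode(m, horizon_h=60.0, grid_h=np.array([0.0, 30.0, 60.0]))
        assert tc["A"][1] == pytest.approx(500.0, rel=1e-4)
        assert tc["A"][2] == pytest.approx(250.0, rel=1e-4)

    def test_osm_alone_never_induces_mmp_or_collagen(self, runs):
        tc = runs["osm_48h"]
        assert tc["mRNA_MMP1"].max() < 1e-6
        assert tc["mRNA_MMP13"].max() < 1e-6

    def test_collagen_and_aggrecan_pools_conserved_along_trajectory(self, model, runs):
        drift = conservation_drift(model, runs["both_act_14d"])
        assert drift["collagen"] < 1e-6
        assert drift["aggrecan"] < 1e-6

    def test_grid_refinement_leaves_day14_readouts_stable(self, model, runs):
        from chondrosim import make_treatment

        sc = make_treatment(model, True, True, True, horizon_h=336.0)
        fine = simulate_ode(model, sc, 336.0, grid_h=np.arange(0.0, 336.5, 0.5))
        coarse = runs["both_act_14d"]
        for sid in ("CollFrag", "AggFrag"):
            rel = abs(fine[sid][-1] - coarse[sid][-1]) / coarse[sid][-1]
            assert rel < 1e-3

    def test_bad_grid_is_rejected(self, model):
        with pytest.raises(ValueError):
            simulate_ode(model, horizon_h=10.0, grid_h=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate_ode(model, horizon_h=10.0, grid_h=np.array([0.0, 20.0]))


class TestReadouts:
    def test_percent_release_zero_fragments(self):
        tc = TimeCourse(np.array([0.0, 1.0]), ["CollFrag"], np.zeros((2, 1)))
        assert np.all(percent_release(tc, "CollFrag", 10000.0) == 0.0)

    def test_percent_release_requires_positive_pool(self):
        tc = TimeCourse(np.array([0.0]), ["X"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            percent_release(tc, "X", 0.0)

    def test_percent_release_is_monotone_for_both_matrix_pools(self, runs):
        for run in ("both_14d", "both_act_14d"):
            for sid in ("CollFrag", "AggFrag"):
                series = percent_release(runs[run], sid, 10000.0)
                assert np.all(np.diff(series) >= -1e-9)

    def test_peak_metrics_calculus_oracle(self):
        """a*t*exp(-t/tau) has its maximum exactly at t=tau."""
        tau = 6.0
        t = np.arange(0.0, 48.0 + 1e-9, 0.25)
        y = 3.0 * t * np.exp(-t / tau)
        tc = TimeCourse(t, ["X"], y[:, None])
        peak_time, peak_value, _, flags = peak_metrics(tc, "X")
        assert abs(peak_time - tau) <= 0.25
        assert peak_value == pytest.approx(3.0 * tau * np.exp(-1), rel=1e-3)
        assert "no interior peak" not in flags

    def test_monotone_trajectory_is_flagged(self):
        t = np.arange(0.0, 10.0, 1.0)
        tc = TimeCourse(t, ["X"], t[:, None])
        peak_time, _, _, flags = peak_metrics(tc, "X")
        assert peak_time == t[-1]
        assert "no interior peak" in flags

    def test_zero_baseline_fold_is_flagged_absolute(self):
        t = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 5.0, 2.0])
        tc = TimeCourse(t, ["X"], y[:, None])
        _, peak_value, fold, flags = peak_metrics(tc, "X")
        assert fold == peak_value == 5.0
        assert any("zero baseline" in f for f in flags)

    def test_mmp13_tracks_mmp1_at_one_tenth(self, runs):
        """Equal decay + 10x transcription means the mRNA ratio is 10
        throughout the induced phase (closed-form limit of the shared ODE)."""
        tc = runs["both_48h"]
        mask = tc.time_h >= 4.0
        ratio = tc["mRNA_MMP1"][mask] / tc["mRNA_MMP13"][mask]
        assert np.allclose(ratio, 10.0, rtol=1e-6)
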