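import numpy as np
import pandas as pd
import pytest

from matchload import (
    FitConfig,
    PlayerParameters,
    PlayerStint,
    build_gd_timeline,
    compile_games,
    cost_function,
    fit_nelder_mead,
    fit_pso,
    generate_recovery_dataset,
    run_player_fit,
    simulate_energy,
)
from matchload.energy import interval_energies
from matchload.fitting import cost_batch, identifiability_flags
from tests.conftest import make_intervals, make_observation


def brute_force_cost(params, games, dt=1.0):
    """Independent oracle: per game, walk the Euler trace minute by
    minute and accumulate squared residuals at measurement boundaries
    (knot-spacing weights), re-anchoring at each contiguous block."""
    total_sse, total_minutes = 0.0, 0.0
    for obs in games:
        trace = simulate_energy(params, obs.timeline, obs.stint, obs.expectation, dt)
        total_minutes += obs.stint.duration
        iv = obs.intervals.sort_values("start_min")
        blocks, cur = [], []
        for row in iv.itertuples():
            if cur and row.start_min > cur[-1].end_min + 1e-6:
                blocks.append(cur)
                cur = []
            cur.append(row)
        if cur:
            blocks.append(cur)
        for block in blocks:
            b0 = block[0].start_min - obs.stint.t_s
            e_anchor = np.interp(b0, trace.tau, trace.cumulative)
            meas, prev = 0.0, b0
            for row in block:
                tau_end = row.end_min - obs.stint.t_s
                meas += row.energy_jkg
                model = np.interp(tau_end, trace.tau, trace.cumulative) - e_anchor
                total_sse += (model - meas) ** 2 * (tau_end - prev)
                prev = tau_end
    return total_sse / total_minutes


@pytest.fixture(scope="module")
def noiseless_player():
    ds = generate_recovery_dataset(n_players=1, noise_sd=0.0, seed=21)
    _, obs = ds.observations()
    return ds.truth["athlete1"], obs["athlete1"]


class TestCostFunction:
    def test_zero_at_generating_parameters(self, noiseless_player):
        truth, games = noiseless_player
        assert cost_function(truth, games) == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_oracle(self, noiseless_player):
        truth, games = noiseless_player
        rng = np.random.default_rng(5)
        for _ in range(3):
            x = truth.to_vector() * rng.uniform(0.8, 1.2, size=11)
            x[10] = np.clip(x[10], 0.5, 1.0)
            params = PlayerParameters.from_vector(x)
            assert cost_function(params, games) == pytest.approx(
                brute_force_cost(params, games), rel=1e-9
            )

    def test_constant_offset_costs_c_squared(self):
        """Measured = model − c at every boundary beyond the first
        interval → ε approaches c² (hand-checkable arithmetic)."""
        tl = build_gd_timeline([], 90.0)
        stint = PlayerStint("p", "g", 0.0, 90.0)
        c, P = 100.0, 600.0
        energies = [5 * P - c] + [5 * P] * 17
        obs = make_observation(tl, stint, "f", energies=energies)
        params = PlayerParameters(np.full((2, 5), P), 1.0)
        # residual is exactly c at all 18 boundaries: ε = Σ c²·5 / 90 = c²
        assert cost_function(params, [obs]) == pytest.approx(c * c)

    def test_two_interval_hand_computation(self):
        tl = build_gd_timeline([], 90.0)
        stint = PlayerStint("p", "g", 0.0, 10.0)
        obs = make_observation(tl, stint, "f", energies=[2000.0, 2600.0])
        params = PlayerParameters(np.full((2, 5), 500.0), 1.0)
        # model cumulative at 5, 10 min: 2500, 5000; measured: 2000, 4600
        expected = ((2500 - 2000) ** 2 * 5 + (5000 - 4600) ** 2 * 5) / 10
        assert cost_function(params, [obs]) == pytest.approx(expected)

    def test_invariant_to_game_ordering(self, noiseless_player):
        truth, games = noiseless_player
        params = PlayerParameters(truth.powers + 37.0, 0.9)
        assert cost_function(params, games) == pytest.approx(
            cost_function(params, list(reversed(games))), rel=1e-12
        )

    def test_gap_in_coverage_reanchors(self):
        """Dropping a middle interval must not leak its energy into later
        residuals: a model that is perfect on the kept intervals scores 0."""
        tl = build_gd_timeline([], 90.0)
        stint = PlayerStint("p", "g", 0.0, 90.0)
        params = PlayerParameters(np.full((2, 5), 500.0), 0.8)
        trace = simulate_energy(params, tl, stint, "f")
        iv = make_intervals(stint, [0.0] * 18)
        iv["energy_jkg"] = interval_energies(trace, iv, stint)
        iv = iv.drop(index=9).reset_index(drop=True)  # gap at [45,50)
        obs = make_observation(tl, stint, "f", intervals=iv)
        assert cost_function(params, [obs]) == pytest.approx(0.0, abs=1e-18)

    def test_no_intervals_rejected(self, flat_timeline, full_stint):
        obs = make_observation(
            flat_timeline, full_stint, "f",
            intervals=make_intervals(full_stint, []),
        )
        with pytest.raises(ValueError):
            compile_games([obs])


class TestNelderMead:
    def test_noiseless_recovery(self, noiseless_player):
        truth, games = noiseless_player
        res = fit_nelder_mead(games, FitConfig(seed=3, n_restarts=3))
        assert np.abs(res.params.powers - truth.powers).max() < 5.0
        assert abs(res.params.eta90 - truth.eta90) < 0.02
        assert res.cost < 1e-3

    def test_descent_from_optimum(self, noiseless_player):
        """A simplex started at the noiseless optimum cannot end above it."""
        from scipy.optimize import minimize

        from matchload.fitting import default_bounds

        truth, games = noiseless_player
        cp = compile_games(games)
        lo, hi = default_bounds()
        z0 = (truth.to_vector() - lo) / (hi - lo)
        f = lambda z: cost_function(lo + np.clip(z, 0, 1) * (hi - lo), cp)
        res = minimize(
            f, z0, method="Nelder-Mead", bounds=[(0.0, 1.0)] * 11,
            options={"adaptive": True},
        )
        assert res.fun <= f(z0) + 1e-15

    def test_seeded_determinism(self, noiseless_player):
        _, games = noiseless_player
        cfg = FitConfig(seed=17, n_restarts=2)
        r1 = fit_nelder_mead(games, cfg)
        r2 = fit_nelder_mead(games, cfg)
        assert r1.cost == r2.cost
        np.testing.assert_array_equal(
            r1.params.to_vector(), r2.params.to_vector()
        )
        assert r1.restart_costs == r2.restart_costs

    def test_perturbing_identifiable_parameter_raises_cost(
        self, noiseless_player
    ):
        truth, games = noiseless_player
        cp = compile_games(games)
        f0 = cost_function(truth, cp)
        x = truth.to_vector()
        for k in range(10):
            for sign in (+1, -1):
                xp = x.copy()
                xp[k] = np.clip(xp[k] + sign * 50.0, 200.0, 800.0)
                assert cost_function(PlayerParameters.from_vector(xp), cp) > f0


class TestPso:
    def test_seeded_determinism(self, noiseless_player):
        _, games = noiseless_player
        cfg = FitConfig(seed=23, n_restarts=1, pso_max_iter=50)
        r1 = fit_pso(games, cfg)
        r2 = fit_pso(games, cfg)
        assert r1.cost == r2.cost
        np.testing.assert_array_equal(r1.params.to_vector(), r2.params.to_vector())

    def test_single_particle_stays_in_box(self, noiseless_player):
        _, games = noiseless_player
        cfg = FitConfig(seed=2, n_restarts=1, pso_particles=1, pso_max_iter=100)
        res = fit_pso(games, cfg)
        x = res.params.to_vector()
        assert np.all(x[:10] >= 200.0) and np.all(x[:10] <= 800.0)
        assert 0.5 <= x[10] <= 1.0

    def test_matches_nelder_mead_on_noiseless_fixture(self, noiseless_player):
        truth, games = noiseless_player
        cfg = FitConfig(seed=5, n_restarts=2)
        nm = fit_nelder_mead(games, cfg)
        pso = fit_pso(games, cfg)
        assert np.abs(pso.params.powers - truth.powers).max() < 5.0
        assert abs(pso.params.eta90 - truth.eta90) < 0.02
        # both should be essentially at the global optimum (cost → 0)
        assert pso.cost < 1e-3 and nm.cost < 1e-3


class TestRunPlayerFit:
    def test_both_methods_reported_with_agreement(self):
        ds = generate_recovery_dataset(n_players=1, noise_sd=120.0, seed=8)
        _, obs = ds.observations()
        out = run_player_fit(obs["athlete1"], FitConfig(seed=9, n_restarts=2))
        assert out["NM"].method == "NM" and out["PSO"].method == "PSO"
        assert out["NM"].n_evaluations > 0 and out["PSO"].n_evaluations > 0
        assert out["agreement"] and out["relative_gap"] < 0.05

    def test_unobserved_cell_flagged_unidentifiable(self, flat_timeline):
        # only GD 0 under favorite is ever observed
        stint = PlayerStint("p", "g", 0.0, 90.0)
        obs = make_observation(flat_timeline, stint, "f", energies=[2500.0] * 18)
        cp = compile_games([obs])
        flags = identifiability_flags(
            PlayerParameters(np.full((2, 5), 500.0), 1.0).to_vector(), cp
        )
        assert flags[2]  # (f, GD 0) identifiable
        assert not flags[[0, 1, 3, 4]].any()  # other favorite GDs are not
        assert not flags[5:].any()  # non-favorite row unobserved

    def test_cost_batch_matches_scalar_path(self, noiseless_player):
        truth, games = noiseless_player
        cp = compile_games(games)
        rng = np.random.default_rng(0)
        X = np.column_stack(
            [rng.uniform(200, 800, size=(6, 10)), rng.uniform(0.5, 1.0, size=6)]
        )
        batch = cost_batch(X, cp)
        singles = [cost_function(x, cp) for x in X]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)
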