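import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matchload import (
    PlayerParameters,
    PlayerStint,
    alpha_from_eta90,
    build_gd_timeline,
    eta,
    interval_energies,
    simulate_energy,
)
from tests.conftest import make_intervals


def closed_form_energy(P, eta90, T):
    """∫₀ᵀ P·e^(−ατ) dτ for constant power — the analytic oracle."""
    if eta90 == 1.0:
        return P * T
    alpha = -np.log(eta90) / 90.0
    return P * (1 - np.exp(-alpha * T)) / alpha


class TestEndurance:
    @pytest.mark.parametrize(
        "eta90,expected",
        [(1.0, 0.0), (0.5, np.log(2) / 90), (0.7, -np.log(0.7) / 90)],
    )
    def test_alpha_formula(self, eta90, expected):
        assert alpha_from_eta90(eta90) == pytest.approx(expected, rel=1e-12)

    def test_alpha_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            alpha_from_eta90(0.0)

    def test_eta_identities(self):
        a = alpha_from_eta90(0.7)
        assert eta(0.0, a) == 1.0
        assert eta(90.0, a) == pytest.approx(0.7, abs=1e-15)
        assert eta(45.0, a) == pytest.approx(np.sqrt(0.7), rel=1e-12)

    def test_round_trip_many_values(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 1.0, size=100)
        recovered = np.array([eta(90.0, alpha_from_eta90(v)) for v in vals])
        assert np.max(np.abs(recovered - vals)) < 1e-12


class TestSimulateEnergy:
    def test_constant_rate_no_decay(self, constant_params, flat_timeline, full_stint):
        trace = simulate_energy(constant_params, flat_timeline, full_stint, "f")
        assert trace.cumulative[0] == 0.0
        assert trace.cumulative[-1] == pytest.approx(600.0 * 90.0)

    def test_euler_matches_closed_form_within_half_percent(
        self, flat_timeline, full_stint
    ):
        for eta90 in (0.5, 0.7, 0.85):
            params = PlayerParameters(np.full((2, 5), 600.0), eta90)
            trace = simulate_energy(params, flat_timeline, full_stint, "f")
            exact = closed_form_energy(600.0, eta90, 90.0)
            rel = abs(trace.cumulative[-1] - exact) / exact
            assert rel < 0.005
            # halving the step shrinks the error
            finer = simulate_energy(params, flat_timeline, full_stint, "f", dt=0.5)
            assert abs(finer.cumulative[-1] - exact) < abs(
                trace.cumulative[-1] - exact
            )

    def test_piecewise_powers_sum_exactly(self, full_stint):
        tl = build_gd_timeline([(30.0, "for")], 90.0)
        powers = np.full((2, 5), 600.0)
        powers[0, 2] = 400.0  # GD 0, favorite
        powers[0, 3] = 700.0  # GD 1, favorite
        params = PlayerParameters(powers, 1.0)
        trace = simulate_energy(params, tl, full_stint, "f")
        assert trace.cumulative[-1] == pytest.approx(400 * 30 + 700 * 60)

    def test_decay_clock_starts_at_stint_entry(self, flat_timeline):
        params = PlayerParameters(np.full((2, 5), 600.0), 0.7)
        late = PlayerStint("p", "g", 45.0, 90.0)
        early = PlayerStint("p", "g", 0.0, 45.0)
        t_late = simulate_energy(params, flat_timeline, late, "f")
        t_early = simulate_energy(params, flat_timeline, early, "f")
        # same playing time from a fresh clock → identical traces
        np.testing.assert_allclose(t_late.cumulative, t_early.cumulative)

    def test_additivity_over_split_stints(self, flat_timeline):
        params = PlayerParameters(np.full((2, 5), 500.0), 0.8)
        whole = simulate_energy(
            params, flat_timeline, PlayerStint("p", "g", 0.0, 90.0), "f"
        )
        first = simulate_energy(
            params, flat_timeline, PlayerStint("p", "g", 0.0, 40.0), "f"
        )
        # continuing from minute 40 with the decay clock carried over
        tail_powers = 500.0 * np.exp(
            -params.alpha * (40.0 + np.arange(50))
        )
        resumed = first.cumulative[-1] + np.sum(tail_powers)
        assert whole.cumulative[-1] == pytest.approx(resumed, rel=1e-12)

    @given(scale=st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_in_power(self, scale):
        flat_timeline = build_gd_timeline([], 90.0)
        full_stint = PlayerStint("p1", "g1", 0.0, 90.0)
        base = PlayerParameters(np.full((2, 5), 400.0), 0.75)
        scaled = PlayerParameters(base.powers * scale, 0.75)
        t1 = simulate_energy(base, flat_timeline, full_stint, "nf")
        t2 = simulate_energy(scaled, flat_timeline, full_stint, "nf")
        np.testing.assert_allclose(t2.cumulative, t1.cumulative * scale, rtol=1e-12)

    def test_no_decay_reduces_to_piecewise_linear(self, full_stint):
        tl = build_gd_timeline([(30.0, "for"), (60.0, "against")], 90.0)
        params = PlayerParameters(
            np.vstack([[300, 400, 500, 600, 700]] * 2), 1.0
        )
        trace = simulate_energy(params, tl, full_stint, "f")
        slopes = np.diff(trace.cumulative)
        np.testing.assert_allclose(slopes[:30], 500.0)
        np.testing.assert_allclose(slopes[30:60], 600.0)
        np.testing.assert_allclose(slopes[60:], 500.0)

    def test_invalid_dt_rejected(self, constant_params, flat_timeline, full_stint):
        with pytest.raises(ValueError):
            simulate_energy(constant_params, flat_timeline, full_stint, "f", dt=0.0)


class TestIntervalEnergies:
    def test_constant_power_interval(self, constant_params, flat_timeline, full_stint):
        trace = simulate_energy(constant_params, flat_timeline, full_stint, "f")
        df = make_intervals(full_stint, [0.0], width=5.0)
        df["start_min"], df["end_min"] = 40.0, 45.0
        assert interval_energies(trace, df, full_stint)[0] == pytest.approx(3000.0)

    def test_interval_energies_telescope(self, flat_timeline, full_stint):
        params = PlayerParameters(np.full((2, 5), 550.0), 0.7)
        trace = simulate_energy(params, flat_timeline, full_stint, "f")
        df = make_intervals(full_stint, [0.0] * 18)
        pred = interval_energies(trace, df, full_stint)
        assert pred.sum() == pytest.approx(trace.cumulative[-1], rel=1e-12)

    def test_decay_makes_equal_state_intervals_decrease(
        self, flat_timeline, full_stint
    ):
        params = PlayerParameters(np.full((2, 5), 550.0), 0.7)
        trace = simulate_energy(params, flat_timeline, full_stint, "f")
        pred = interval_energies(
            trace, make_intervals(full_stint, [0.0] * 18), full_stint
        )
        assert np.all(np.diff(pred) < 0)

    def test_interval_outside_stint_rejected(
        self, constant_params, flat_timeline
    ):
        stint = PlayerStint("p", "g", 0.0, 45.0)
        trace = simulate_energy(constant_params, flat_timeline, stint, "f")
        df = make_intervals(stint, [0.0])
        df["start_min"], df["end_min"] = 43.0, 48.0
        with pytest.raises(ValueError):
            interval_energies(trace, df, stint)
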