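"""Forward model of cumulative energy expenditure over a stint.

A player's instantaneous power output depends on the current goal
difference d(t) and the pre-game expectation class e, damped by an
exponential endurance factor η(τ) = exp(−ατ) on the playing-time clock τ
(τ = 0 at stint entry). Cumulative energy solves

    dE/dτ = P(d(t_s + τ), e) · η(τ),    E(0) = 0,

integrated with the explicit Euler method on a Δt = 1 min grid, with the
goal difference looked up at the left endpoint of each step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    EXPECTATION_CLASSES,
    GD_LEVELS,
    REFERENCE_MINUTES,
    EnergyTrace,
    GoalDiffTimeline,
    PlayerParameters,
    PlayerStint,
)

__all__ = [
    "alpha_from_eta90",
    "eta",
    "simulate_energy",
    "interval_energies",
    "trace_frame",
    "step_grid",
]


def alpha_from_eta90(eta90: float) -> float:
    """Per-minute decay rate from the endurance coefficient.

    α = −ln(η90)/90, so that exp(−α·90) = η90 exactly. ``eta90 = 1``
    means no decay.
    """
    if not eta90 > 0:
        raise ValueError("eta90 must be positive")
    return -float(np.log(eta90)) / REFERENCE_MINUTES


def eta(tau, alpha: float):
    """Power-consumption efficiency exp(−α·τ) at playing time ``tau``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    out = np.exp(-alpha * tau)
    return out if out.ndim else float(out)


def step_grid(duration: float, dt: float):
    """Left endpoints and widths of the Euler steps covering [0, duration].

    The last step is shortened if ``duration`` is not a multiple of ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_full = int(np.floor(duration / dt + 1e-9))
    tau_left = np.arange(n_full, dtype=float) * dt
    dtau = np.full(n_full, dt, dtype=float)
    rem = duration - n_full * dt
    if rem > 1e-9:
        tau_left = np.append(tau_left, n_full * dt)
        dtau = np.append(dtau, rem)
    return tau_left, dtau


def simulate_energy(
    params: PlayerParameters,
    timeline: GoalDiffTimeline,
    stint: PlayerStint,
    expectation: str,
    dt: float = 1.0,
) -> EnergyTrace:
    """Euler-integrate the energy model over one stint.

    Parameters
    ----------
    params
        State powers (J/kg/min) and endurance coefficient.
    timeline
        Clipped goal-difference timeline of the game.
    stint
        Entry/exit minutes; the decay clock τ starts at entry.
    expectation
        ``"f"`` (favorite) or ``"nf"``; selects the power row.
    dt
        Euler step in minutes (default 1).

    Returns
    -------
    EnergyTrace
        Grid [0, t_e − t_s] with E(0) = 0 and cumulative J/kg.
    """
    if expectation not in EXPECTATION_CLASSES:
        raise ValueError(f"expectation must be one of {EXPECTATION_CLASSES}")
    if stint.t_e > timeline.duration + 1e-9:
        raise ValueError("stint extends past game duration")
    tau_left, dtau = step_grid(stint.duration, dt)
    gd = np.asarray(timeline.value_at(stint.t_s + tau_left))
    p_row = params.power_row(expectation)
    powers = p_row[gd - min(GD_LEVELS)]
    effs = np.exp(-params.alpha * tau_left)
    increments = powers * effs * dtau
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    grid = np.concatenate([[0.0], tau_left + dtau])
    return EnergyTrace(
        tau=grid, cumulative=cumulative, t_start=stint.t_s, gd=gd, eta=effs
    )


def interval_energies(
    trace: EnergyTrace,
    intervals: pd.DataFrame,
    stint: PlayerStint,
) -> np.ndarray:
    """Predicted energy per measured interval from a cumulative trace.

    Each interval [start, end) maps to E(end − t_s) − E(start − t_s);
    endpoints between grid nodes are linearly interpolated (exact on the
    1-min grid with integer-minute intervals).
    """
    start = np.asarray(intervals["start_min"], dtype=float) - stint.t_s
    end = np.asarray(intervals["end_min"], dtype=float) - stint.t_s
    T = trace.tau[-1]
    if np.any(start < -1e-9) or np.any(end > T + 1e-9):
        raise ValueError("interval outside the simulated stint")
    e_start = np.interp(start, trace.tau, trace.cumulative)
    e_end = np.interp(end, trace.tau, trace.cumulative)
    return e_end - e_start


def trace_frame(trace: EnergyTrace) -> pd.DataFrame:
    """Trace as a tidy table (tau_min, game_min, gd, eta,
    cumulative_energy_jkg) for CSV export."""
    n_steps = len(trace.tau) - 1
    gd = trace.gd if trace.gd is not None else np.full(n_steps, np.nan)
    effs = trace.eta if trace.eta is not None else np.full(n_steps, np.nan)
    return pd.DataFrame(
        {
            "tau_min": trace.tau,
            "game_min": trace.t_start + trace.tau,
            "gd": np.concatenate([gd[:1], gd]) if n_steps else [np.nan],
            "eta": np.concatenate([effs[:1], effs]) if n_steps else [np.nan],
            "cumulative_energy_jkg": trace.cumulative,
        }
    )
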