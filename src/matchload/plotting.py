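"""Optional matplotlib views of a player profile.

Plain renderings of the profile document: a radar of state powers, an
influence-matrix heatmap, and a measured-vs-modelled overlay for one
game. All functions return the Axes so callers can restyle or save.
"""

from __future__ import annotations

import numpy as np

from .energy import simulate_energy
from .types import (
    EXPECTATION_CLASSES,
    GD_LEVELS,
    GameObservation,
    PlayerParameters,
)
from .profiling import InfluenceMatrix


def plot_power_radar(params: PlayerParameters, ax=None):
    """Radar of the ten state powers, one trace per expectation class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.linspace(0, 2 * np.pi, len(GD_LEVELS), endpoint=False)
    for i, e in enumerate(EXPECTATION_CLASSES):
        vals = params.powers[i]
        ax.plot(
            np.append(angles, angles[0]),
            np.append(vals, vals[0]),
            label={"f": "favorite", "nf": "non-favorite"}[e],
        )
    ax.set_xticks(angles)
    ax.set_xticklabels([f"GD {d}" for d in GD_LEVELS])
    ax.set_title(f"State powers (J/kg/min), η90={params.eta90:.2f}")
    ax.legend(loc="lower right", bbox_to_anchor=(1.2, -0.1))
    return ax


def plot_influence_heatmap(infl: InfluenceMatrix, ax=None):
    """2×5 heatmap of influence values; masked cells are blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.4))
    data = np.ma.masked_invalid(infl.g)
    im = ax.imshow(data, cmap="RdYlGn", vmin=0.5, vmax=1.5, aspect="auto")
    ax.set_xticks(range(5), [str(d) for d in GD_LEVELS])
    ax.set_yticks(range(2), ["f", "nf"])
    ax.set_xlabel("goal difference")
    for (i, j), v in np.ndenumerate(infl.g):
        if np.isfinite(v):
            ax.text(j, i, f"{v:.2f}", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="influence g")
    return ax


def plot_game_overlay(params: PlayerParameters, obs: GameObservation, ax=None):
    """Measured vs modelled cumulative energy over one stint, with the
    GD timeline shaded underneath."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    trace = simulate_energy(params, obs.timeline, obs.stint, obs.expectation)
    ax.plot(trace.t_start + trace.tau, trace.cumulative, label="model", color="tab:orange")
    if len(obs.intervals):
        ends = obs.intervals["end_min"].to_numpy(float)
        meas = np.cumsum(obs.intervals["energy_jkg"].to_numpy(float))
        ax.step(
            np.concatenate([[obs.stint.t_s], ends]),
            np.concatenate([[0.0], meas]),
            where="post", label="measured", color="tab:blue",
        )
    ax2 = ax.twinx()
    bp = np.append(obs.timeline.breakpoints, obs.timeline.duration)
    ax2.step(bp, np.append(obs.timeline.values, obs.timeline.values[-1]),
             where="post", color="gray", alpha=0.4)
    ax2.set_ylabel("GD")
    ax.set_xlabel("game minute")
    ax.set_ylabel("cumulative energy (J/kg)")
    ax.set_title(f"{obs.player_id} — {obs.game_id} ({obs.expectation})")
    ax.legend()
    return ax
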