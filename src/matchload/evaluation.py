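"""Baselines and regression metrics.

The fitted model is compared against two simple predictors: B1 uses the
mean observed power per goal difference and B2 the median, both with no
endurance decay (η = 1) and no expectation split. All methods are scored
on the same observation level — predicted vs measured energy per
5-minute interval — with MAE, RMSE and MSE per player, then mean and
standard deviation across players.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energy import interval_energies, simulate_energy
from .types import GD_LEVELS, GameObservation, PlayerParameters

__all__ = [
    "BaselineParameters",
    "baseline_powers",
    "predict_intervals",
    "compute_metrics",
    "aggregate_metrics",
    "metrics_table",
]


@dataclass
class BaselineParameters:
    """Powers per GD (J/kg/min) shared across expectations, η fixed at 1.

    ``power_per_gd`` maps gd → power; GDs never observed fall back to
    ``fallback`` (the statistic over all intervals) and are recorded in
    ``missing``.
    """

    method: str  # "mean" or "median"
    power_per_gd: dict[int, float]
    fallback: float
    missing: tuple[int, ...] = ()

    def power(self, gd: int) -> float:
        return self.power_per_gd.get(int(gd), self.fallback)


def baseline_powers(labeled: pd.DataFrame, method: str = "mean") -> BaselineParameters:
    """Per-GD mean or median observed power from labelled intervals.

    Power of an interval is its energy divided by its length in minutes.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    if not len(labeled):
        raise ValueError("no labelled intervals to build a baseline from")
    lengths = labeled["end_min"].to_numpy(float) - labeled["start_min"].to_numpy(float)
    power = labeled["energy_jkg"].to_numpy(float) / lengths
    stat = np.mean if method == "mean" else np.median
    fallback = float(stat(power))
    per_gd: dict[int, float] = {}
    missing = []
    gd = labeled["gd"].to_numpy(int)
    for d in GD_LEVELS:
        sel = gd == d
        if sel.any():
            per_gd[d] = float(stat(power[sel]))
        else:
            missing.append(d)
    return BaselineParameters(
        method=method, power_per_gd=per_gd, fallback=fallback,
        missing=tuple(missing),
    )


def predict_intervals(
    params: PlayerParameters | BaselineParameters,
    games: Sequence[GameObservation],
    dt: float = 1.0,
) -> np.ndarray:
    """Predicted energy per labelled interval, concatenated across games.

    Model parameters go through the Euler trace; baseline parameters
    predict P_gd × interval length with no decay. The output aligns with
    the row order of each game's interval table.
    """
    parts = []
    for obs in games:
        if not len(obs.intervals):
            continue
        if isinstance(params, PlayerParameters):
            trace = simulate_energy(
                params, obs.timeline, obs.stint, obs.expectation, dt=dt
            )
            parts.append(interval_energies(trace, obs.intervals, obs.stint))
        else:
            lengths = (
                obs.intervals["end_min"].to_numpy(float)
                - obs.intervals["start_min"].to_numpy(float)
            )
            p = np.array([params.power(d) for d in obs.intervals["gd"]])
            parts.append(p * lengths)
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def measured_energies(games: Sequence[GameObservation]) -> np.ndarray:
    """Measured interval energies in the same order as predictions."""
    parts = [
        obs.intervals["energy_jkg"].to_numpy(float)
        for obs in games
        if len(obs.intervals)
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def compute_metrics(predicted, measured) -> dict[str, float]:
    """MAE, RMSE and MSE between paired predictions and measurements."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one pair")
    resid = predicted - measured
    mse = float(np.mean(resid**2))
    return {
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(mse)),
        "mse": mse,
    }


def aggregate_metrics(per_player: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Mean and standard deviation of each metric across players, per
    method. Sample standard deviation (ddof=1) by default."""
    rows = []
    for method, grp in per_player.groupby("method", sort=True):
        row = {"method": method, "n_players": len(grp)}
        for m in ("mae", "rmse", "mse"):
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_std"] = float(grp[m].std(ddof=ddof)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_table(
    player_games: dict[str, Sequence[GameObservation]],
    fitted: dict[str, dict[str, PlayerParameters]],
    baselines: tuple[str, ...] = ("mean", "median"),
) -> pd.DataFrame:
    """Per-player metric rows for fitted models and baselines.

    ``fitted`` maps player_id → {label → PlayerParameters}; labels become
    ``model_<label>`` rows. Baselines are rebuilt per player from that
    player's labelled intervals (B1 = mean, B2 = median).
    """
    rows = []
    for pid, games in player_games.items():
        games = [g for g in games if len(g.intervals)]
        if not games:
            continue
        measured = measured_energies(games)
        labeled = pd.concat([g.intervals for g in games], ignore_index=True)
        methods: dict[str, PlayerParameters | BaselineParameters] = {}
        for label, params in fitted.get(pid, {}).items():
            methods[f"model_{label}"] = params
        for b_label, b_method in zip(("B1", "B2"), baselines):
            methods[b_label] = baseline_powers(labeled, b_method)
        for label, params in methods.items():
            pred = predict_intervals(params, games)
            rows.append(
                {"player_id": pid, "method": label, **compute_metrics(pred, measured)}
            )
    return pd.DataFrame(rows)
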