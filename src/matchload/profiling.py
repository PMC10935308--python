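"""Player profiles: minutes ledger and influence matrix.

The influence matrix g turns absolute state powers into a dimensionless
profile. For each goal difference d a reference power r_d is the
minutes-weighted mean of the favorite and non-favorite powers; each
cell's influence is g_{e,d} = P_{d,e} / r_d. Values above 1 mean elevated
effort in that state relative to the player's own GD-level norm; cells
with no observed minutes are undefined (masked).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import compute_metrics, measured_energies, predict_intervals
from .fitting import FitResult
from .types import (
    EXPECTATION_CLASSES,
    GD_LEVELS,
    GameObservation,
    PlayerParameters,
)

__all__ = [
    "MinutesLedger",
    "InfluenceMatrix",
    "minutes_ledger",
    "influence_matrix",
    "profile_report",
    "save_profile",
    "load_profile",
]

#: Empirical band the influence values are expected to occupy; values
#: outside only trigger a report note, never clipping.
INFLUENCE_TYPICAL_RANGE = (0.5, 1.5)


@dataclass
class MinutesLedger:
    """Labelled playing minutes per (expectation, GD) cell, shape (2, 5)."""

    minutes: np.ndarray

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (2, 5):
            raise ValueError("minutes must have shape (2, 5)")
        if np.any(self.minutes < 0):
            raise ValueError("minutes must be non-negative")

    @property
    def per_gd(self) -> np.ndarray:
        """Row sums t_d across expectations, shape (5,)."""
        return self.minutes.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.minutes.sum())


@dataclass
class InfluenceMatrix:
    """Reference powers r_d and influence values g_{e,d}.

    ``g`` is NaN (and ``defined`` False) in cells with zero minutes;
    ``r`` is NaN for GDs never observed under either expectation.
    """

    r: np.ndarray  # shape (5,)
    g: np.ndarray  # shape (2, 5)
    defined: np.ndarray  # bool, shape (2, 5)


def minutes_ledger(labeled: pd.DataFrame) -> MinutesLedger:
    """Sum labelled interval lengths into (expectation, GD) cells."""
    minutes = np.zeros((2, 5))
    if len(labeled):
        lengths = (
            labeled["end_min"].to_numpy(float) - labeled["start_min"].to_numpy(float)
        )
        e_idx = np.array(
            [EXPECTATION_CLASSES.index(e) for e in labeled["expectation"]]
        )
        d_idx = labeled["gd"].to_numpy(int) - min(GD_LEVELS)
        np.add.at(minutes, (e_idx, d_idx), lengths)
    return MinutesLedger(minutes=minutes)


def influence_matrix(
    params: PlayerParameters, ledger: MinutesLedger
) -> InfluenceMatrix:
    """Influence g_{e,d} = P_{d,e} / r_d with minutes-weighted reference.

    r_d pools both expectation classes: r_d = Σ_e P_{d,e}·t_{d,e} / t_d.
    The minutes-weighted mean of g across expectations is therefore 1 for
    every GD with observed minutes. When the defined powers at a GD are
    identical the reference equals that power exactly, so g is exactly 1.
    """
    t = ledger.minutes
    t_d = ledger.per_gd
    if not np.any(t_d > 0):
        raise ValueError("ledger has no observed minutes at any GD")
    r = np.full(5, np.nan)
    g = np.full((2, 5), np.nan)
    defined = t > 0
    for d in range(5):
        if t_d[d] <= 0:
            continue
        p_col = params.powers[:, d]
        obs = defined[:, d]
        p_obs = p_col[obs]
        if np.all(p_obs == p_obs[0]):
            r[d] = float(p_obs[0])  # exact unit influence for equal powers
        else:
            r[d] = float(np.dot(p_col[obs], t[obs, d]) / t_d[d])
        g[obs, d] = p_col[obs] / r[d]
    return InfluenceMatrix(r=r, g=g, defined=defined)


def profile_report(
    player_id: str,
    fits: dict[str, FitResult],
    ledger: MinutesLedger,
    games: Optional[Sequence[GameObservation]] = None,
    reference_method: str = "NM",
) -> dict:
    """Assemble a player's profile document.

    Contains the fitted powers and endurance per method, the influence
    matrix of the reference method, the minutes ledger, identifiability
    flags and (when ``games`` are given) per-game fit summaries of the
    reference method. The document is plain JSON-serialisable data and
    round-trips losslessly through :func:`save_profile` /
    :func:`load_profile`.
    """
    if reference_method not in fits:
        raise ValueError(f"reference method {reference_method!r} not in fits")
    ref = fits[reference_method]
    infl = influence_matrix(ref.params, ledger)
    notes = []
    finite = infl.g[np.isfinite(infl.g)]
    lo, hi = INFLUENCE_TYPICAL_RANGE
    if finite.size and (finite.min() < lo or finite.max() > hi):
        notes.append(
            f"influence values outside the typical {lo}-{hi} band; "
            "interpret low-minutes cells with caution"
        )
    doc = {
        "player_id": player_id,
        "methods": {label: fr.to_dict() for label, fr in fits.items()},
        "reference_method": reference_method,
        "influence": {
            "r_per_gd": _tolist(infl.r),
            "g": {
                e: _tolist(infl.g[i]) for i, e in enumerate(EXPECTATION_CLASSES)
            },
            "defined": {
                e: [bool(b) for b in infl.defined[i]]
                for i, e in enumerate(EXPECTATION_CLASSES)
            },
            "gd_levels": list(GD_LEVELS),
        },
        "minutes": {
            e: _tolist(ledger.minutes[i]) for i, e in enumerate(EXPECTATION_CLASSES)
        },
        "minutes_per_gd": _tolist(ledger.per_gd),
        "notes": notes,
    }
    if games is not None:
        per_game = []
        for obs in games:
            if not len(obs.intervals):
                continue
            pred = predict_intervals(ref.params, [obs])
            meas = measured_energies([obs])
            per_game.append(
                {
                    "game_id": obs.game_id,
                    "expectation": obs.expectation,
                    "stint": [obs.stint.t_s, obs.stint.t_e],
                    "n_intervals": int(len(obs.intervals)),
                    **compute_metrics(pred, meas),
                }
            )
        doc["per_game"] = per_game
    return doc


def _tolist(arr: np.ndarray) -> list:
    return [None if not np.isfinite(v) else float(v) for v in arr]


def save_profile(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_profile(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
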