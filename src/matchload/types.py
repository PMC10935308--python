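"""Core domain containers shared across the pipeline.

The modelling unit is a player's stint in one game: a goal-difference
timeline d(t), a pre-game expectation class e ∈ {f, nf}, and the 5-minute
energy-expenditure records measured while the player was on the pitch.
A player's season is a list of :class:`GameObservation` objects; the model
itself is a :class:`PlayerParameters` vector (ten state powers plus the
endurance coefficient η90).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Goal-difference levels retained by the analysis; running scores outside
#: this band are clipped onto the border values.
GD_LEVELS: tuple[int, ...] = (-2, -1, 0, 1, 2)

#: Expectation classes the model distinguishes (favorite / non-favorite).
EXPECTATION_CLASSES: tuple[str, str] = ("f", "nf")

#: Box constraints on the optimisation variables.
POWER_LOWER, POWER_UPPER = 200.0, 800.0
ETA90_LOWER, ETA90_UPPER = 0.5, 1.0

#: Reference playing time (minutes) at which the endurance coefficient is
#: defined: η(90) = η90.
REFERENCE_MINUTES = 90.0

N_PARAMS = 11  # 5 GD levels × 2 expectation classes + η90

#: Parameter names in optimisation-vector order.
PARAM_NAMES: tuple[str, ...] = tuple(
    f"P_{d}_{e}" for e in EXPECTATION_CLASSES for d in GD_LEVELS
) + ("eta90",)


@dataclass(frozen=True)
class Expectation:
    """Pre-game expectation derived from win/lose betting probabilities.

    ``ratio`` is p_win / p_lose; ``category`` is the three-way label
    (favorite / close / underdog) kept for metadata, while ``model_class``
    is the two-way pooling actually used by the model: favorite → ``"f"``,
    close and underdog → ``"nf"``.
    """

    ratio: float
    category: str
    model_class: str


@dataclass(frozen=True)
class GoalEvent:
    """A goal at ``minute`` scored by the observed team (``side="for"``)
    or conceded (``side="against"``)."""

    minute: float
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("for", "against"):
            raise ValueError(f"side must be 'for' or 'against', got {self.side!r}")
        if self.minute < 0:
            raise ValueError("goal minute must be non-negative")


@dataclass(frozen=True)
class PlayerStint:
    """A player's continuous on-pitch span within one game."""

    player_id: str
    game_id: str
    t_s: float
    t_e: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_s < self.t_e):
            raise ValueError(
                f"invalid stint [{self.t_s}, {self.t_e}) for {self.player_id}"
            )

    @property
    def duration(self) -> float:
        return self.t_e - self.t_s


@dataclass
class GoalDiffTimeline:
    """Piecewise-constant goal difference over game time.

    Segments are right-open: the value at a goal minute is the new score.
    ``values`` are clipped to the GD band; ``raw_values`` keep the
    unclipped running margin for audit.
    """

    breakpoints: np.ndarray  # segment start minutes, breakpoints[0] == 0
    values: np.ndarray  # clipped GD per segment
    duration: float
    raw_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=int)
        if self.breakpoints[0] != 0.0:
            raise ValueError("timeline must start at minute 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.values.min() < min(GD_LEVELS) or self.values.max() > max(GD_LEVELS):
            raise ValueError("timeline values must lie in the clipped GD band")

    def value_at(self, t) -> np.ndarray | int:
        """Clipped GD at game minute(s) ``t`` (right-open segments;
        ``t == duration`` returns the final value)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0) or np.any(t_arr > self.duration + 1e-9):
            raise ValueError("time outside [0, duration]")
        idx = np.searchsorted(self.breakpoints, t_arr, side="right") - 1
        out = self.values[idx]
        return out if t_arr.ndim else int(out)


@dataclass
class PlayerParameters:
    """The per-player model: state powers and endurance.

    ``powers`` has shape (2, 5): rows follow :data:`EXPECTATION_CLASSES`
    (favorite, non-favorite), columns follow :data:`GD_LEVELS`. Powers are
    in J/kg per minute. ``eta90`` ∈ [0.5, 1] is the fraction of initial
    power retained at 90 playing minutes; the decay rate is
    α = −ln(η90)/90 per minute.
    """

    powers: np.ndarray
    eta90: float

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if self.powers.shape != (2, 5):
            raise ValueError("powers must have shape (2, 5)")
        if not (0.0 < self.eta90 <= 1.0):
            raise ValueError("eta90 must lie in (0, 1]")

    @property
    def alpha(self) -> float:
        return -float(np.log(self.eta90)) / REFERENCE_MINUTES

    def power(self, gd: int, expectation: str) -> float:
        return float(
            self.powers[EXPECTATION_CLASSES.index(expectation), gd - min(GD_LEVELS)]
        )

    def power_row(self, expectation: str) -> np.ndarray:
        """Powers indexed by gd+2 for one expectation class."""
        return self.powers[EXPECTATION_CLASSES.index(expectation)]

    def to_vector(self) -> np.ndarray:
        """Flatten to the 11-dim optimisation vector
        (P_-2_f … P_2_f, P_-2_nf … P_2_nf, η90)."""
        return np.concatenate([self.powers.ravel(), [self.eta90]])

    @classmethod
    def from_vector(cls, x: Sequence[float]) -> "PlayerParameters":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_PARAMS,):
            raise ValueError(f"expected vector of length {N_PARAMS}")
        return cls(powers=x[:10].reshape(2, 5).copy(), eta90=float(x[10]))

    def to_dict(self) -> dict:
        d = {
            name: float(v)
            for name, v in zip(PARAM_NAMES[:10], self.powers.ravel())
        }
        d["eta90"] = float(self.eta90)
        return d


@dataclass
class EnergyTrace:
    """Cumulative modelled energy over one stint on the Euler grid.

    ``tau`` are playing-time minutes from stint entry (``tau[0] == 0``);
    ``cumulative`` is E(τ) in J/kg with E(0) = 0.
    """

    tau: np.ndarray
    cumulative: np.ndarray
    t_start: float = 0.0  # game minute of stint entry
    gd: Optional[np.ndarray] = None  # GD at the left endpoint of each step
    eta: Optional[np.ndarray] = None  # efficiency at the left endpoint


@dataclass
class GameObservation:
    """Everything the model needs about one (player, game) pair.

    ``intervals`` is the labelled-interval table for the stint with columns
    ``start_min, end_min, energy_jkg, gd, tau_start`` (game-clock minutes).
    """

    player_id: str
    game_id: str
    timeline: GoalDiffTimeline
    stint: PlayerStint
    expectation: str  # "f" or "nf"
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.expectation not in EXPECTATION_CLASSES:
            raise ValueError(f"expectation must be one of {EXPECTATION_CLASSES}")
        if self.stint.t_e > self.timeline.duration + 1e-9:
            raise ValueError("stint extends past game duration")
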