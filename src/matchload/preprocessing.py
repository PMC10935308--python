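"""From raw fixtures to labelled energy observations.

Inputs are four tidy CSV tables (odds per game, goal events, player
stints, 5-minute energy records). Preprocessing derives the pre-game
expectation from the win/lose probability ratio, builds the clipped
goal-difference timeline of each game, and joins both onto every measured
interval that falls inside a player's stint and is flagged as active
play. Records flagged as non-play (pre-kickoff warm-up, halftime dressing
room) are discarded.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    GD_LEVELS,
    Expectation,
    GameObservation,
    GoalDiffTimeline,
    GoalEvent,
    PlayerStint,
)

__all__ = [
    "compute_expectation",
    "build_gd_timeline",
    "label_intervals",
    "load_inputs",
    "build_observations",
    "FAVORITE_RATIO",
    "UNDERDOG_RATIO",
]

#: Expectation-ratio thresholds: e ≥ 2 → favorite (inclusive), e < 0.5 →
#: underdog, otherwise a close game. Favorite maps to model class "f";
#: close and underdog are pooled into "nf".
FAVORITE_RATIO = 2.0
UNDERDOG_RATIO = 0.5

INPUT_FILES = {
    "fixtures": ["game_id", "p_win", "p_draw", "p_lose", "duration"],
    "goals": ["game_id", "minute", "side"],
    "stints": ["player_id", "game_id", "t_s", "t_e"],
    "energy": [
        "player_id",
        "game_id",
        "start_min",
        "end_min",
        "energy_jkg",
        "playing_flag",
    ],
}


def compute_expectation(p_win: float, p_lose: float) -> Expectation:
    """Classify a game from pre-game win/lose probabilities.

    The ratio e = p_win / p_lose is thresholded: favorite when e ≥ 2
    (boundary inclusive), underdog when e < 0.5, close otherwise. The
    two-way model class pools close and underdog into non-favorite.
    """
    if p_win < 0 or p_lose < 0 or p_win > 1 or p_lose > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if p_win == 0 and p_lose == 0:
        raise ValueError("p_win and p_lose cannot both be zero")
    if p_lose == 0:
        warnings.warn(
            "p_lose is zero; expectation ratio treated as +inf (favorite)",
            stacklevel=2,
        )
        ratio = float("inf")
    else:
        ratio = p_win / p_lose
    if ratio >= FAVORITE_RATIO:
        category = "favorite"
    elif ratio < UNDERDOG_RATIO:
        category = "underdog"
    else:
        category = "close"
    return Expectation(
        ratio=ratio,
        category=category,
        model_class="f" if category == "favorite" else "nf",
    )


def build_gd_timeline(
    events: Iterable[GoalEvent | tuple], duration: float
) -> GoalDiffTimeline:
    """Running goal difference, clipped segment-wise onto {−2 … 2}.

    Goals add +1 (``for``) / −1 (``against``) to the raw margin in event
    order (stable sort by minute); each goal opens a new right-open
    segment starting at its minute. The game starts at 0.
    """
    evs = [e if isinstance(e, GoalEvent) else GoalEvent(*e) for e in events]
    for e in evs:
        if e.minute > duration:
            raise ValueError(f"goal at minute {e.minute} beyond duration {duration}")
    evs.sort(key=lambda e: e.minute)  # Python sort is stable: ties keep input order
    breakpoints = [0.0]
    raw = [0]
    for e in evs:
        margin = raw[-1] + (1 if e.side == "for" else -1)
        if e.minute == breakpoints[-1]:
            raw[-1] = margin  # goal exactly at an existing breakpoint
        else:
            breakpoints.append(float(e.minute))
            raw.append(margin)
    raw_arr = np.array(raw, dtype=int)
    clipped = np.clip(raw_arr, min(GD_LEVELS), max(GD_LEVELS))
    return GoalDiffTimeline(
        breakpoints=np.array(breakpoints),
        values=clipped,
        duration=float(duration),
        raw_values=raw_arr,
    )


def label_intervals(
    intervals: pd.DataFrame,
    timeline: GoalDiffTimeline,
    stint: PlayerStint,
    expectation: Expectation | str,
    min_overlap: Optional[float] = None,
) -> pd.DataFrame:
    """Attach GD and expectation labels to the intervals of one stint.

    Drops records whose ``playing_flag`` is false and records that are not
    contained in the half-open stint [t_s, t_e). With the default
    ``min_overlap=None`` an interval must be fully contained; a numeric
    value keeps intervals overlapping the stint by at least that many
    minutes (their energies are used unscaled).

    Returns a copy with columns ``gd`` (clipped GD at the interval start),
    ``expectation`` (model class) and ``tau_start`` (playing-time minute
    at the interval start).
    """
    model_class = (
        expectation.model_class if isinstance(expectation, Expectation) else expectation
    )
    df = intervals.copy()
    if "playing_flag" in df.columns:
        df = df[df["playing_flag"].astype(bool)]
    if min_overlap is None:
        keep = (df["start_min"] >= stint.t_s - 1e-9) & (
            df["end_min"] <= stint.t_e + 1e-9
        )
    else:
        overlap = np.minimum(df["end_min"], stint.t_e) - np.maximum(
            df["start_min"], stint.t_s
        )
        keep = overlap >= min_overlap - 1e-9
    df = df[keep].sort_values("start_min").reset_index(drop=True)
    if len(df):
        start_clip = np.maximum(df["start_min"].to_numpy(float), stint.t_s)
        df["gd"] = np.asarray(timeline.value_at(np.minimum(start_clip, timeline.duration)))
        df["tau_start"] = start_clip - stint.t_s
    else:
        df["gd"] = pd.Series(dtype=int)
        df["tau_start"] = pd.Series(dtype=float)
    df["expectation"] = model_class
    return df


def load_inputs(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the four input CSVs from a directory, validating columns."""
    data_dir = Path(data_dir)
    out = {}
    for name, cols in INPUT_FILES.items():
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing required input file: {path}")
        df = pd.read_csv(path)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{path} lacks columns {sorted(missing)}")
        out[name] = df
    return out


def build_observations(
    fixtures: pd.DataFrame,
    goals: pd.DataFrame,
    stints: pd.DataFrame,
    energy: pd.DataFrame,
    min_overlap: Optional[float] = None,
) -> tuple[pd.DataFrame, dict[str, list[GameObservation]]]:
    """Assemble per-(player, game) observations from the raw tables.

    Returns the concatenated labelled-interval table and a mapping
    player_id → list of :class:`GameObservation` (one per stint that
    retained at least one labelled interval; stints with none are kept
    with an empty table so minutes ledgers stay complete).
    """
    timelines: dict[str, GoalDiffTimeline] = {}
    expectations: dict[str, Expectation] = {}
    for _, row in fixtures.iterrows():
        gid = str(row["game_id"])
        game_goals = goals[goals["game_id"].astype(str) == gid]
        timelines[gid] = build_gd_timeline(
            list(zip(game_goals["minute"], game_goals["side"])),
            float(row["duration"]),
        )
        expectations[gid] = compute_expectation(
            float(row["p_win"]), float(row["p_lose"])
        )

    labeled_parts = []
    observations: dict[str, list[GameObservation]] = {}
    for _, row in stints.iterrows():
        pid, gid = str(row["player_id"]), str(row["game_id"])
        if gid not in timelines:
            raise ValueError(f"stint references unknown game {gid}")
        stint = PlayerStint(pid, gid, float(row["t_s"]), float(row["t_e"]))
        mask = (energy["player_id"].astype(str) == pid) & (
            energy["game_id"].astype(str) == gid
        )
        labelled = label_intervals(
            energy[mask], timelines[gid], stint, expectations[gid], min_overlap
        )
        labelled["game_id"] = gid
        labelled["player_id"] = pid
        obs = GameObservation(
            player_id=pid,
            game_id=gid,
            timeline=timelines[gid],
            stint=stint,
            expectation=expectations[gid].model_class,
            intervals=labelled,
        )
        observations.setdefault(pid, []).append(obs)
        if len(labelled):
            labeled_parts.append(labelled)
    labeled = (
        pd.concat(labeled_parts, ignore_index=True)
        if labeled_parts
        else pd.DataFrame(
            columns=["player_id", "game_id", "start_min", "end_min", "energy_jkg",
                     "gd", "tau_start", "expectation"]
        )
    )
    keep_cols = [
        c
        for c in [
            "player_id", "game_id", "start_min", "end_min", "energy_jkg",
            "gd", "expectation", "tau_start",
        ]
        if c in labeled.columns
    ]
    return labeled[keep_cols] if len(labeled) else labeled, observations
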