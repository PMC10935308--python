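"""Per-player parameter estimation.

The 11-dimensional parameter vector (ten state powers, η90) is estimated
by minimising a squared-error cost between the Euler-integrated energy
trace and the measured cumulative energy, normalised by total minutes
played:

    ε(x) = Σ_j ∫ (E_j(x, t) − E_measured,j(t))² dt  /  Σ_j (t_e,j − t_s,j)

Measured cumulative energy is known at 5-minute interval boundaries, so
the integral is sampled there: the squared difference between the model
trace and the measured cumulative at each boundary is weighted by the
boundary spacing. Where labelled coverage has gaps (discarded halftime
or partial records) the comparison is re-anchored at the start of each
contiguous block of labelled intervals, so only measured increments are
ever compared with model increments; with gap-free coverage this reduces
to plain cumulative energy from stint entry, and a perfect model has
exactly zero cost on noiseless data.

Two derivative-free optimisers minimise ε under box constraints: the
Nelder–Mead simplex (scipy, candidate points clipped into the box) and an
in-package global-best particle swarm. Both run in coordinates normalised
to the unit box and repeat from multiple seeded restarts, keeping the
best result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .energy import step_grid
from .types import (
    ETA90_LOWER,
    ETA90_UPPER,
    EXPECTATION_CLASSES,
    GD_LEVELS,
    N_PARAMS,
    POWER_LOWER,
    POWER_UPPER,
    REFERENCE_MINUTES,
    GameObservation,
    PlayerParameters,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "CompiledPlayer",
    "compile_games",
    "cost_batch",
    "cost_function",
    "fit_nelder_mead",
    "fit_pso",
    "run_player_fit",
    "identifiability_flags",
    "default_bounds",
]


def default_bounds() -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) arrays for the 11-dim optimisation vector."""
    lo = np.array([POWER_LOWER] * 10 + [ETA90_LOWER])
    hi = np.array([POWER_UPPER] * 10 + [ETA90_UPPER])
    return lo, hi


@dataclass
class FitConfig:
    """Optimiser settings shared by both methods.

    Restart initial points are drawn uniformly within the bounds from a
    generator seeded by ``seed``; the first Nelder–Mead restart starts at
    the box midpoint. All tolerances act in unit-box coordinates.
    """

    n_restarts: int = 10
    seed: Optional[int] = None
    bounds: Optional[tuple[np.ndarray, np.ndarray]] = None
    # Nelder–Mead
    nm_xatol: float = 1e-7
    nm_fatol_rel: float = 1e-6  # × cost at the start point
    nm_maxfev: int = 20000
    # particle swarm
    pso_particles: int = 25
    pso_inertia: tuple[float, float] = (0.9, 0.4)  # linear schedule start → end
    pso_cognitive: float = 1.49
    pso_social: float = 1.49
    pso_max_iter: int = 1500
    pso_stagnation: int = 100
    pso_stagnation_rtol: float = 1e-12
    pso_max_kicks: int = 5
    pso_velocity_clamp: float = 0.5  # fraction of the unit box
    # diagnostics
    agreement_threshold: float = 0.05
    identifiability_delta: float = 50.0  # J/kg/min probe on each power
    identifiability_rtol: float = 1e-9

    def get_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.bounds if self.bounds is not None else default_bounds()


@dataclass
class FitResult:
    """Outcome of one optimisation method for one player."""

    params: PlayerParameters
    cost: float
    n_evaluations: int
    method: str
    restart_costs: list[float] = field(default_factory=list)
    convergence_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    identifiable: Optional[np.ndarray] = None  # per power cell, shape (10,)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "x_hat": self.params.to_dict(),
            "alpha": self.params.alpha,
            "cost": float(self.cost),
            "n_evaluations": int(self.n_evaluations),
            "restart_costs": [float(c) for c in self.restart_costs],
        }
        if self.identifiable is not None:
            d["identifiable"] = [bool(b) for b in self.identifiable]
        return d


@dataclass
class CompiledPlayer:
    """A player's games flattened into arrays for fast cost evaluation.

    Steps of all games are concatenated. ``cell`` maps each Euler step to
    a power-vector entry (e·5 + gd + 2); ``anchor`` indexes the padded
    cumulative sum at the start of the step's labelled block (0 = zero
    energy); ``target`` is the measured cumulative energy relative to that
    anchor at the step's right endpoint; ``weight`` is 1 on steps covered
    by labelled intervals and 0 elsewhere.
    """

    cell: np.ndarray
    tau_left: np.ndarray
    dtau: np.ndarray
    anchor: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    total_minutes: float
    n_intervals: int
    minutes_per_cell: np.ndarray  # labelled minutes per power cell, shape (10,)

    @property
    def n_steps(self) -> int:
        return len(self.cell)


def _contiguous_blocks(intervals, stint) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group labelled intervals into contiguous blocks in τ coordinates.

    Returns per block (knot τ positions, measured cumulative values
    relative to the block start).
    """
    if not len(intervals):
        return []
    start = np.maximum(intervals["start_min"].to_numpy(float), stint.t_s) - stint.t_s
    end = np.minimum(intervals["end_min"].to_numpy(float), stint.t_e) - stint.t_s
    energy = intervals["energy_jkg"].to_numpy(float)
    order = np.argsort(start)
    start, end, energy = start[order], end[order], energy[order]
    blocks = []
    b_start = 0
    for k in range(1, len(start) + 1):
        if k == len(start) or start[k] > end[k - 1] + 1e-6:
            s, e, en = start[b_start:k], end[b_start:k], energy[b_start:k]
            knots_tau = np.concatenate([s[:1], e])
            knots_val = np.concatenate([[0.0], np.cumsum(en)])
            blocks.append((knots_tau, knots_val))
            b_start = k
    return blocks


def compile_games(
    games: Sequence[GameObservation], dt: float = 1.0
) -> CompiledPlayer:
    """Flatten a player's games for vectorised cost evaluation."""
    if not games:
        raise ValueError("no games to compile")
    cells, taus, dtaus, anchors, targets, weights = [], [], [], [], [], []
    total_minutes = 0.0
    n_intervals = 0
    minutes_per_cell = np.zeros(10)
    offset = 0  # global step index of the current game's first step
    for obs in games:
        stint = obs.stint
        total_minutes += stint.duration
        tau_left, dtau = step_grid(stint.duration, dt)
        K = len(tau_left)
        gd = np.asarray(obs.timeline.value_at(stint.t_s + tau_left))
        e_idx = EXPECTATION_CLASSES.index(obs.expectation)
        cells.append(e_idx * 5 + gd - min(GD_LEVELS))
        taus.append(tau_left)
        dtaus.append(dtau)
        tau_end = tau_left + dtau
        anchor = np.full(K, 0, dtype=np.int64)
        target = np.zeros(K)
        weight = np.zeros(K)
        for knots_tau, knots_val in _contiguous_blocks(obs.intervals, stint):
            b0 = knots_tau[0]
            m = int(np.round(b0 / dt))
            if abs(m * dt - b0) > 1e-6:
                raise ValueError(
                    "labelled interval boundaries must lie on the Euler grid"
                )
            # residuals are evaluated at the measurement boundaries, each
            # weighted by its knot spacing (the cost integral sampled at
            # the resolution the data defines); cumulative values are
            # relative to the block start so gaps never leak offsets
            prev = b0
            for kt, kv in zip(knots_tau[1:], knots_val[1:]):
                s = int(np.searchsorted(tau_end, kt - 1e-9))  # step ending at kt
                if not (0 <= s < K) or abs(tau_end[s] - kt) > 1e-6:
                    raise ValueError(
                        "labelled interval boundaries must lie on the Euler grid"
                    )
                anchor[s] = offset + m  # padded-cumsum index of E(b0)
                target[s] = kv
                weight[s] = (kt - prev) / dtau[s]
                prev = kt
        anchors.append(anchor)
        targets.append(target)
        weights.append(weight)
        if len(obs.intervals):
            n_intervals += len(obs.intervals)
            lab = obs.intervals
            lengths = np.minimum(lab["end_min"], stint.t_e) - np.maximum(
                lab["start_min"], stint.t_s
            )
            cell_ids = e_idx * 5 + lab["gd"].to_numpy(int) - min(GD_LEVELS)
            np.add.at(minutes_per_cell, cell_ids, np.asarray(lengths, dtype=float))
        offset += K
    if n_intervals == 0:
        raise ValueError("player has no labelled intervals")
    if total_minutes <= 0:
        raise ValueError("zero total minutes played")
    return CompiledPlayer(
        cell=np.concatenate(cells),
        tau_left=np.concatenate(taus),
        dtau=np.concatenate(dtaus),
        anchor=np.concatenate(anchors),
        target=np.concatenate(targets),
        weight=np.concatenate(weights),
        total_minutes=total_minutes,
        n_intervals=n_intervals,
        minutes_per_cell=minutes_per_cell,
    )


def cost_batch(X: np.ndarray, cp: CompiledPlayer) -> np.ndarray:
    """Cost ε for a batch of parameter vectors, shape (n, 11) → (n,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = X[:, :10]
    alpha = -np.log(X[:, 10]) / REFERENCE_MINUTES
    rates = P[:, cp.cell] * np.exp(-np.outer(alpha, cp.tau_left))
    cs = np.cumsum(rates * cp.dtau, axis=1)
    cs_pad = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    resid = cs - cs_pad[:, cp.anchor] - cp.target
    sse = (resid * resid * (cp.weight * cp.dtau)).sum(axis=1)
    return sse / cp.total_minutes


def cost_function(
    x: PlayerParameters | np.ndarray,
    games: Sequence[GameObservation] | CompiledPlayer,
) -> float:
    """ε(x) for a single parameter vector over a player's games."""
    cp = games if isinstance(games, CompiledPlayer) else compile_games(games)
    vec = x.to_vector() if isinstance(x, PlayerParameters) else np.asarray(x)
    return float(cost_batch(vec[None, :], cp)[0])


def _norm(x, lo, hi):
    return (x - lo) / (hi - lo)


def _denorm(z, lo, hi):
    return lo + z * (hi - lo)


def fit_nelder_mead(
    games: Sequence[GameObservation] | CompiledPlayer,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Best-of-restarts Nelder–Mead minimisation of ε.

    Runs in unit-box coordinates with scipy's bounded simplex (candidate
    points clipped into the box). The first restart starts at the box
    midpoint, the rest at uniform random points.
    """
    config = config or FitConfig()
    cp = games if isinstance(games, CompiledPlayer) else compile_games(games)
    lo, hi = config.get_bounds()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    trace: list[float] = []
    n_eval = 0

    def f(z):
        nonlocal n_eval
        n_eval += 1
        c = float(cost_batch(_denorm(np.clip(z, 0, 1), lo, hi)[None, :], cp)[0])
        trace.append(min(c, trace[-1]) if trace else c)
        return c

    best = None
    restart_costs = []
    errors = []
    for r in range(config.n_restarts):
        z0 = np.full(N_PARAMS, 0.5) if r == 0 else rng.uniform(size=N_PARAMS)
        f0 = f(z0)
        try:
            res = minimize(
                f,
                z0,
                method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * N_PARAMS,
                options={
                    "xatol": config.nm_xatol,
                    "fatol": config.nm_fatol_rel * max(f0, 1e-30),
                    "maxfev": config.nm_maxfev,
                    "adaptive": True,
                },
            )
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(exc)
            continue
        restart_costs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"Nelder–Mead failed on all restarts: {errors}")
    x_hat = _denorm(np.clip(best.x, 0, 1), lo, hi)
    result = FitResult(
        params=PlayerParameters.from_vector(x_hat),
        cost=float(best.fun),
        n_evaluations=n_eval,
        method="NM",
        restart_costs=restart_costs,
        convergence_trace=np.asarray(trace),
    )
    result.identifiable = identifiability_flags(x_hat, cp, config)
    return result


def fit_pso(
    games: Sequence[GameObservation] | CompiledPlayer,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Best-of-restarts global-best particle swarm minimisation of ε.

    Standard velocity/position updates in the unit box with a linearly
    decaying inertia weight and velocity clamped to half the box width.
    Bounds are absorbing: positions are clipped into the box and the
    velocity component of any clipped coordinate is zeroed, which stops
    box faces from acting as spurious attractors. When the global best
    stalls for
    ``pso_stagnation`` iterations the worst half of the swarm is
    re-scattered uniformly (forgetting its personal bests) to restore
    diversity; a restart stops after ``pso_max_iter`` iterations or after
    ``pso_max_kicks`` consecutive re-scatters without improvement.
    """
    config = config or FitConfig()
    cp = games if isinstance(games, CompiledPlayer) else compile_games(games)
    lo, hi = config.get_bounds()
    ss = np.random.SeedSequence(config.seed).spawn(config.n_restarts + 1)

    n_p = config.pso_particles
    w0, w1 = config.pso_inertia
    vmax = config.pso_velocity_clamp
    trace: list[float] = []
    n_eval = 0

    best_x, best_f = None, np.inf
    restart_costs = []
    for r in range(config.n_restarts):
        rng = np.random.default_rng(ss[r + 1])
        pos = rng.uniform(size=(n_p, N_PARAMS))
        vel = rng.uniform(-vmax, vmax, size=(n_p, N_PARAMS)) * 0.1
        fvals = cost_batch(_denorm(pos, lo, hi), cp)
        n_eval += n_p
        pbest, pbest_f = pos.copy(), fvals.copy()
        g_i = int(np.argmin(pbest_f))
        gbest, gbest_f = pbest[g_i].copy(), float(pbest_f[g_i])
        trace.append(min(gbest_f, trace[-1]) if trace else gbest_f)
        stagnant = 0
        kicks = 0
        for it in range(config.pso_max_iter):
            w = w0 + (w1 - w0) * it / max(config.pso_max_iter - 1, 1)
            r1 = rng.random((n_p, N_PARAMS))
            r2 = rng.random((n_p, N_PARAMS))
            vel = (
                w * vel
                + config.pso_cognitive * r1 * (pbest - pos)
                + config.pso_social * r2 * (gbest - pos)
            )
            np.clip(vel, -vmax, vmax, out=vel)
            pos = pos + vel
            # absorbing walls: clip to the box and kill the velocity of
            # clipped components, so faces cannot become attractors
            out_of_box = (pos < 0.0) | (pos > 1.0)
            np.clip(pos, 0.0, 1.0, out=pos)
            vel[out_of_box] = 0.0
            fvals = cost_batch(_denorm(pos, lo, hi), cp)
            n_eval += n_p
            improved = fvals < pbest_f
            pbest[improved] = pos[improved]
            pbest_f[improved] = fvals[improved]
            g_i = int(np.argmin(pbest_f))
            if pbest_f[g_i] < gbest_f * (1 - config.pso_stagnation_rtol):
                stagnant = 0
                kicks = 0
            else:
                stagnant += 1
            if pbest_f[g_i] < gbest_f:
                gbest, gbest_f = pbest[g_i].copy(), float(pbest_f[g_i])
            trace.append(min(gbest_f, trace[-1]))
            if stagnant >= config.pso_stagnation:
                kicks += 1
                if kicks > config.pso_max_kicks or n_p < 2:
                    break
                # diversity kick: re-scatter the worst half of the swarm
                worst = np.argsort(pbest_f)[n_p // 2:]
                pos[worst] = rng.uniform(size=(len(worst), N_PARAMS))
                vel[worst] = rng.uniform(-vmax, vmax, size=(len(worst), N_PARAMS))
                pbest[worst] = pos[worst]
                pbest_f[worst] = cost_batch(_denorm(pos[worst], lo, hi), cp)
                n_eval += len(worst)
                stagnant = 0
        restart_costs.append(gbest_f)
        if gbest_f < best_f:
            best_x, best_f = gbest, gbest_f
    x_hat = _denorm(best_x, lo, hi)
    result = FitResult(
        params=PlayerParameters.from_vector(x_hat),
        cost=float(best_f),
        n_evaluations=n_eval,
        method="PSO",
        restart_costs=restart_costs,
        convergence_trace=np.asarray(trace),
    )
    result.identifiable = identifiability_flags(x_hat, cp, config)
    return result


def identifiability_flags(
    x_hat: np.ndarray,
    cp: CompiledPlayer,
    config: Optional[FitConfig] = None,
) -> np.ndarray:
    """Flat-cost probe: a power cell is unidentifiable when perturbing it
    by ±delta (clipped to the box) leaves the cost unchanged — which
    happens exactly for (GD, expectation) states with zero labelled
    minutes."""
    config = config or FitConfig()
    lo, hi = config.get_bounds()
    x_hat = np.asarray(x_hat, dtype=float)
    f0 = float(cost_batch(x_hat[None, :], cp)[0])
    probes = []
    for k in range(10):
        for sign in (+1, -1):
            x = x_hat.copy()
            x[k] = np.clip(x[k] + sign * config.identifiability_delta, lo[k], hi[k])
            probes.append(x)
    fvals = cost_batch(np.array(probes), cp).reshape(10, 2)
    change = np.abs(fvals - f0).max(axis=1)
    return change > config.identifiability_rtol * (1.0 + abs(f0))


def run_player_fit(
    games: Sequence[GameObservation],
    config: Optional[FitConfig] = None,
) -> dict:
    """Fit one player with both optimisers and compare the costs.

    Returns ``{"NM": FitResult, "PSO": FitResult, "agreement": bool,
    "relative_gap": float}``. Agreement compares only runs where both
    methods optimise the same identifiable landscape; the relative gap is
    |ε_PSO − ε_NM| / min(ε).
    """
    config = config or FitConfig()
    cp = compile_games(games)
    nm = fit_nelder_mead(cp, config)
    pso = fit_pso(cp, config)
    denom = min(nm.cost, pso.cost)
    gap = abs(nm.cost - pso.cost) / denom if denom > 0 else 0.0
    return {
        "NM": nm,
        "PSO": pso,
        "agreement": gap <= config.agreement_threshold,
        "relative_gap": gap,
    }
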