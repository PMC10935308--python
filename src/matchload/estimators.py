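"""scikit-learn-style estimators over the fitting and baseline machinery.

The sample unit is a :class:`~matchload.types.GameObservation`: ``X`` is
a sequence of observations for one player and predictions are energies
(J/kg) per labelled 5-minute interval, concatenated in observation
order. ``y`` is accepted for API compatibility but the measured energies
live inside the observations, so it may be omitted.

Both estimators follow the usual conventions — ``get_params`` /
``set_params``, fitted attributes with a trailing underscore, and
``score`` inherited from :class:`~sklearn.base.RegressorMixin` (R² on
interval energies) — so they compose with sklearn model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import (
    BaselineParameters,
    baseline_powers,
    measured_energies,
    predict_intervals,
)
from .fitting import FitConfig, compile_games, fit_nelder_mead, fit_pso
from .types import GameObservation

__all__ = ["EnduranceEnergyRegressor", "GoalDifferenceBaseline"]


def _validate_games(X) -> list[GameObservation]:
    games = list(X)
    if not games:
        raise ValueError("X must contain at least one game observation")
    for g in games:
        if not isinstance(g, GameObservation):
            raise TypeError(
                "X must be a sequence of GameObservation, got "
                f"{type(g).__name__}"
            )
    if not any(len(g.intervals) for g in games):
        raise ValueError("no labelled intervals in any observation")
    return games


class EnduranceEnergyRegressor(RegressorMixin, BaseEstimator):
    """Per-player energy model fitted by derivative-free optimisation.

    Estimates the ten (GD, expectation) state powers and the endurance
    coefficient η90 by minimising the squared cumulative-energy error
    against the measured 5-minute records, using the Nelder–Mead simplex,
    a particle swarm, or both (keeping the lower-cost solution as the
    prediction parameters).

    Parameters
    ----------
    optimizer : {"nelder-mead", "pso", "both"}
    n_restarts : int
        Seeded restarts per optimiser; the best restart wins.
    random_state : int or None
        Seeds restart initial points and the swarm.
    fit_options : dict or None
        Extra :class:`~matchload.fitting.FitConfig` fields.

    Attributes
    ----------
    params_ : PlayerParameters
        Parameters used by :meth:`predict` (lowest-cost method).
    cost_ : float
        Cost ε at ``params_`` ((J/kg)² per minute played).
    results_ : dict
        Method label → :class:`~matchload.fitting.FitResult`.
    agreement_ : bool or None
        With ``optimizer="both"``, whether the two costs agree within the
        configured relative threshold.
    """

    def __init__(
        self,
        optimizer: str = "nelder-mead",
        n_restarts: int = 10,
        random_state: Optional[int] = None,
        fit_options: Optional[dict] = None,
    ):
        self.optimizer = optimizer
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.fit_options = fit_options

    def _config(self) -> FitConfig:
        opts = dict(self.fit_options or {})
        return FitConfig(
            n_restarts=self.n_restarts, seed=self.random_state, **opts
        )

    def fit(self, X: Sequence[GameObservation], y=None):
        if self.optimizer not in ("nelder-mead", "pso", "both"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        games = _validate_games(X)
        config = self._config()
        cp = compile_games(games)
        results = {}
        if self.optimizer in ("nelder-mead", "both"):
            results["NM"] = fit_nelder_mead(cp, config)
        if self.optimizer in ("pso", "both"):
            results["PSO"] = fit_pso(cp, config)
        best = min(results.values(), key=lambda r: r.cost)
        self.results_ = results
        self.params_ = best.params
        self.cost_ = best.cost
        self.best_method_ = best.method
        if len(results) == 2:
            gap = abs(results["NM"].cost - results["PSO"].cost)
            denom = min(r.cost for r in results.values())
            self.relative_gap_ = gap / denom if denom > 0 else 0.0
            self.agreement_ = self.relative_gap_ <= config.agreement_threshold
        else:
            self.relative_gap_ = None
            self.agreement_ = None
        self.n_games_ = len(games)
        return self

    def predict(self, X: Sequence[GameObservation]) -> np.ndarray:
        check_is_fitted(self, "params_")
        return predict_intervals(self.params_, _validate_games(X))

    def score(self, X, y=None, sample_weight=None):
        games = _validate_games(X)
        if y is None:
            y = measured_energies(games)
        return super().score(games, y, sample_weight)


class GoalDifferenceBaseline(RegressorMixin, BaseEstimator):
    """Mean- or median-power-per-GD baseline (no decay, no expectation).

    Predicts interval energy as P_gd × interval length, where P_gd is the
    mean (B1) or median (B2) observed power among training intervals at
    that goal difference; unseen GDs fall back to the all-interval
    statistic.
    """

    def __init__(self, statistic: str = "mean"):
        self.statistic = statistic

    def fit(self, X: Sequence[GameObservation], y=None):
        import pandas as pd

        games = _validate_games(X)
        labeled = pd.concat(
            [g.intervals for g in games if len(g.intervals)], ignore_index=True
        )
        self.baseline_: BaselineParameters = baseline_powers(labeled, self.statistic)
        self.power_per_gd_ = dict(self.baseline_.power_per_gd)
        return self

    def predict(self, X: Sequence[GameObservation]) -> np.ndarray:
        check_is_fitted(self, "baseline_")
        return predict_intervals(self.baseline_, _validate_games(X))

    def score(self, X, y=None, sample_weight=None):
        games = _validate_games(X)
        if y is None:
            y = measured_energies(games)
        return super().score(games, y, sample_weight)
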