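# matchload

Individual performance profiling for soccer players from GPS external-load
data. Given per-player energy expenditure recorded in 5-minute intervals
(J/kg), goal timings, pre-game betting odds and substitution minutes,
`matchload` fits a per-player model of how effort responds to the scoreline
and to pre-game expectations, and turns the fit into an interpretable
player profile.

It is written for sports scientists and performance analysts who want an
individualised alternative to position- or league-level scoreline studies:
one model per player, estimated from that player's own season.

## Model

A player's instantaneous power output (J/kg per minute) depends on the
current goal difference *d* ∈ {−2, −1, 0, 1, 2} (clipped; ±2 absorb larger
margins) and the pre-game expectation class *e* ∈ {f, nf} (favorite when
the win/lose probability ratio p_win/p_lose ≥ 2, non-favorite otherwise),
damped by exponential endurance decay on the playing-time clock τ:

    dE/dτ = P(d(t_s + τ), e) · η(τ),     η(τ) = e^(−ατ),     E(0) = 0,

with α = −ln(η90)/90, so η90 ∈ [0.5, 1] is the fraction of initial power a
player retains at 90 playing minutes. The parameter vector per player is

    x = (P_{−2,f}, …, P_{2,f}, P_{−2,nf}, …, P_{2,nf}, η90),

with 200 ≤ P ≤ 800 J/kg/min. The equation is integrated by explicit Euler
with Δt = 1 min. Parameters are estimated by minimising the squared
difference between the modelled cumulative energy and the measured
cumulative energy at the 5-minute record boundaries, normalised by total
minutes played,

    ε(x) = Σ_j ∫ (E_j(x,t) − E_measured,j(t))² dt  /  Σ_j (t_e,j − t_s,j),

with two derivative-free optimisers under box constraints — the
Nelder–Mead simplex and a global-best particle swarm — each restarted 10
times. Agreement of the two methods is reported as a reliability check.
Fits are compared against two baselines: B1 (mean observed power per goal
difference, no decay) and B2 (median), scored by MAE/RMSE/MSE on interval
energies. A fitted player is summarised by the influence matrix
g_{e,d} = P_{d,e} / r_d, where r_d is the minutes-weighted mean power at
goal difference d; g > 1 marks states where the player works harder than
their own GD-level norm.

A synthetic season generator with known ground-truth parameters stands in
for proprietary GPS data, so every stage is testable end to end.

## Worked example

```python
import matchload as ml

# a small synthetic season: 3 players, 6 games, everyone plays
ds = ml.generate_dataset(ml.SyntheticConfig(seed=9, n_players=3, n_games=6,
                                            participation_prob=1.0))
labeled, observations = ds.observations()

games = observations["athlete1"]
est = ml.EnduranceEnergyRegressor(optimizer="both", n_restarts=10,
                                  random_state=4).fit(games)
print(f"best method {est.best_method_}, cost {est.cost_:.1f}")
print(f"eta90 {est.params_.eta90:.3f} (truth {ds.truth['athlete1'].eta90:.3f})")

base = ml.GoalDifferenceBaseline("mean").fit(games)
meas = ml.evaluation.measured_energies(games)
m_model = ml.compute_metrics(est.predict(games), meas)
m_base = ml.compute_metrics(base.predict(games), meas)
print(f"model MAE {m_model['mae']:.1f} J/kg vs B1 MAE {m_base['mae']:.1f} J/kg")
```

prints

```
best method PSO, cost 43720.2
eta90 0.783 (truth 0.778)
model MAE 118.1 J/kg vs B1 MAE 223.9 J/kg
```

The cost is the per-minute squared cumulative-energy error of the best
fit; η90 ≈ 0.78 means the player retains about 78% of initial power at 90
playing minutes (recovered within 0.005 of the generating value here); the
model's per-interval MAE is about half the mean-power baseline's, because
the baseline ignores both the expectation split and the endurance decay.

The same pipeline runs from the shell:

```sh
matchload run-all --synthetic --out runs/demo --seed 4 --restarts 10
matchload run-all --data-dir my_season/ --out runs/real   # fixtures.csv,
                                  # goals.csv, stints.csv, energy.csv
```

writing `labeled.csv`, `fit_results.json`, `metrics.csv`,
`profile_<player>.json` and a `manifest.json` with artifact checksums.

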