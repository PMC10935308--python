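# Methods

## The model

`matchload` models a soccer player's external load — energy expenditure in
J/kg derived from GPS metabolic power, aggregated into 5-minute records —
as the integral of a state-dependent power output damped by endurance
decay. The state is the pair (goal difference, pre-game expectation):

* **Goal difference** d(t) ∈ {−2, −1, 0, 1, 2} is piecewise constant over
  game time, clipped at ±2 (being 3 up is treated like being 2 up).
  Segments are right-open: the new value applies from the goal minute on.
* **Expectation** e ∈ {f, nf}: a game is *favorite* when the pre-game
  win/lose probability ratio is ≥ 2 (boundary inclusive), *underdog* below
  0.5, *close* otherwise; underdog and close are pooled as non-favorite
  because underdog games are rare for a top team. The three-way category is
  kept as metadata only.
* **Endurance** η(τ) = e^(−ατ) with α = −ln(η90)/90 acts on the playing-time
  clock τ (zero at the player's entry minute, not at kickoff). η90 is the
  fraction of initial power retained at 90 playing minutes; τ > 90 simply
  continues the decay.

Cumulative energy over a stint solves dE/dτ = P(d(t_s+τ), e)·η(τ), E(0)=0,
integrated by explicit Euler with Δt = 1 min and the goal difference looked
up at the left endpoint of each step (goals at fractional minutes take
effect at the next grid point). The per-player parameter vector is the ten
state powers plus η90; powers are bounded to [200, 800] J/kg/min (≈1,000 to
4,000 J/kg per 5-minute record) and η90 to [0.5, 1].

## The cost and its sampling grid

The fit minimises the squared difference between modelled and measured
cumulative energy, integrated over each stint and divided by total minutes
played. Measured cumulative energy is only known at the 5-minute record
boundaries, so the integral is sampled there: each boundary residual is
weighted by its spacing to the previous boundary. We deliberately do not
interpolate the measured curve to the 1-minute grid — the model curve is
convex between boundaries whenever η < 1, so comparing it against a
linearly interpolated measured curve injects an irreducible discretisation
error (≈10 (J/kg)²/min on typical players) that makes even a perfect model
score nonzero. Sampling at the boundaries keeps the estimator unbiased at
the truth: on noiseless synthetic data the generating parameters score
exactly zero.

Where labelled coverage has gaps — records flagged as non-play (pre-kickoff,
halftime dressing room) or partially outside the stint are discarded — the
comparison is re-anchored at the start of each contiguous block of labelled
records: measured increments within the block are compared with model
increments over the same span. With gap-free coverage this is identical to
plain cumulative energy from stint entry, and it prevents a discarded
record's unknown energy from contaminating every later residual. The
denominator remains the total stint minutes.

## Optimisation

Both fitters work in unit-box-normalised coordinates (powers span 600
units, η90 spans 0.5; normalising keeps simplex and swarm steps isotropic)
and repeat from 10 restarts, keeping the best.

* **Nelder–Mead**: scipy's bounded simplex (candidates clipped into the
  box), adaptive coefficients for dimension 11, `xatol = 1e-7` in
  normalised units, `fatol` scaled to 1e-6 of the start-point cost, at most
  20,000 evaluations per restart. The first restart starts at the box
  midpoint, the rest at uniform random points.
* **Particle swarm** (global-best, 25 particles): inertia decays linearly
  0.9 → 0.4 over at most 1,500 iterations, cognitive = social = 1.49,
  velocity clamped to half the box width. Bounds are *absorbing*: positions
  are clipped and the velocity component of a clipped coordinate is zeroed.
  This matters: with plain clipping the box faces become attractors — for a
  fixed face the remaining problem is convex with a unique constrained
  minimum, and swarms reproducibly converged to such face minima far above
  the global optimum. When the global best stalls for 100 iterations the
  worst half of the swarm is re-scattered uniformly (personal bests
  forgotten); after 5 fruitless re-scatters the restart stops.

The landscape is benign in the powers (for fixed η90 the model is linear in
P, hence the cost convex) and curved mainly along η90, which is why the
simplex converges in a few thousand evaluations while the swarm needs tens
of thousands — the evaluation-count ordering, not its exact values, is the
reproducible fact. Agreement between the two methods (relative cost gap,
default flag threshold 5%) is a per-player reliability check.

**Identifiability.** A (GD, expectation) cell with zero labelled minutes
leaves its power unconstrained. After each fit every power is probed ±50
J/kg/min (clipped); a cost change below 1e-9·(1+ε) marks the parameter
unidentifiable. Such cells stay in the 11-dim vector but are flagged
low-confidence in reports and masked in the influence matrix.

## Baselines and metrics

B1 predicts interval energy as (mean observed power at that GD) × length,
B2 uses the median; both set η = 1 and pool the two expectation classes —
this asymmetry against the model is intentional, they are the "scoreline
only" comparators. All methods are scored on the same observation level
(predicted vs measured 5-minute energies) with MAE, RMSE and MSE per
player; aggregates weight players equally and use the sample standard
deviation (ddof = 1, configurable).

## Influence matrix

For each GD d the reference power r_d is the minutes-weighted mean of the
favorite and non-favorite powers, and g_{e,d} = P_{d,e}/r_d. The
minutes-weighted mean of g across expectations is exactly 1 per GD
(conservation), g is invariant to rescaling all powers, and when the
observed powers at a GD are equal the reference is set to that power so g
is exactly 1 in floating point. Values typically fall in 0.5–1.5; the
range is empirical and never enforced — out-of-band values only add a note
to the profile document.

## Synthetic data

The generator emulates the shape of a single-team top-division season:

* **Defaults**: 19 players, 33 games, favorite share 21/33, 90-minute
  games, 5-minute records, interval noise SD 150 J/kg (additive Gaussian,
  truncated at zero — a record cannot be negative).
* **Odds ↔ goals consistency**: each game draws (team, opponent) Poisson
  scoring rates — favorite context 2.0 vs 0.8 goals/90, non-favorite 1.05
  vs 1.35, lognormal jitter SD 0.12 — and the pre-game odds are the exact
  Skellam win/draw/lose probabilities of those rates. The expectation label
  recovered from the odds therefore matches the process that generated the
  goals, and favorite-heavy schedules skew goal-difference minutes positive
  with GD 0 dominant, as real seasons of a strong team look.
* **Stints**: full 90 with probability 0.7, otherwise a sub-off (exit
  60–85) or sub-on (entry 45–70) at whole minutes, as match sheets record
  them; whole minutes also keep record boundaries on the Euler grid.
* **Flags**: the record starting at minute 45 is emitted with
  `playing_flag = false` by default (halftime in the dressing room);
  preprocessing discards it.
* **Ground truth**: per-player powers uniform in [250, 750], η90 in
  [0.55, 0.95]; noiseless record energies are exactly the forward model's.

A second entry point, `generate_recovery_dataset`, uses four scripted goal
timelines per expectation class (built-up lead, built-up deficit, goalless,
and a −1→+2 swing) so every player observes all ten (e, d) cells for at
least 20–160 minutes. The Poisson season cannot guarantee this — trailing
by two as a heavy favorite is rare by construction — so recovery and
method-comparison studies use the scripted fixture, optionally with an
enforced favorite/non-favorite power gap (≥100 J/kg/min at chosen GDs) and
capped η90.

What the generator does *not* emulate: within-interval autocorrelation of
effort, tactical regimes, stoppage time (duration is configurable but
defaults to 90), opponent-specific effects, or sensor dropout. Passing
recovery tests therefore demonstrates the estimation machinery is correct
under the model's own assumptions, not that real players follow the model.

## Problem sizes

Validation studies use 5 players (noiseless recovery and noisy NM/PSO
agreement, 8 games each, best-of-10 restarts) and 20 players for the
baseline comparison; these sizes give stable aggregate statistics while a
full run of the suite stays in the minutes range on a single core.

## Known limitations

* Powers are assumed constant across a season; form changes alias into the
  state powers.
* A record straddling a goal keeps the goal-difference label of its start
  minute (the forward model does track the change minute by minute).
* The expectation split is binary; with league-wide data a three-way or
  continuous expectation would be identifiable.
* No uncertainty quantification beyond restart spread and the NM/PSO gap;
  point estimates only.
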