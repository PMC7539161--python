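# Methods

This note documents the models, numerical choices and known limitations of
`cgmforecast`, in the package's own terms.

## Data model and units

All glucose values are mg/dL (mmol/L conversion, ×18.016, belongs at the
I/O boundary and is not performed internally). Timestamps are naive local
wall-clock time, because the clock features (time of day, day of week) are
behavioural. Series carry a nominal step of 5 minutes; every spacing
comparison tolerates ±1 minute of sensor timestamp jitter. Values are
clamped to the standard CGM reporting range [40, 400] mg/dL on validation.
Duplicate timestamps keep the last record (a later upload supersedes an
earlier one). A gap is any inter-sample spacing above 15 minutes (three
missed 5-minute points) plus the jitter tolerance; supervised windows and
prediction features are only ever taken from gap-free stretches, and no
imputation is performed anywhere — fabricating ground truth would corrupt
both training targets and evaluation references.

## On-board kinetics

Insulin-on-board (IOB) and carbs-on-board (COB) use linear decay:
remaining = dose · max(0, 1 − elapsed/D), with D the insulin action
duration `dia` (default 240 min, typical for rapid-acting analogues) or the
carb absorption duration `cad` (default 180 min, a mixed meal). Linear
curves are the simplest kinetics that conserve the dose (the utilisation
rate integrates to the dose) and reach exactly zero at D; the curve is a
pluggable function, so a bi-exponential profile can be substituted without
touching feature code. Only `bolus` events enter IOB — basal insulin is
background and is deliberately excluded, following the usual
bolus-calculator convention; only `meal` events enter COB.

Personalisation: once ≥25 meal/bolus events have clean post-event coverage
(inside a gap-free segment with ≥30 min of following data), `dia` and `cad`
are chosen by grid search (dia ∈ 120…360, cad ∈ 90…300, 30-min spacing)
minimising the residual sum of squares of a one-step linear response model
Δg ≈ a + b·(carb rate) + c·(insulin rate). Below the threshold, a simpler
sign-up-information estimate is available: each event's remainder is its
dose discounted by the observed glucose change since the event relative to
its expected total effect (expected rise carbs·CF/ICR for meals, expected
fall units·CF for insulin), floored at zero and capped at the dose. On
simulator data the grid fit recovers the generating durations exactly at
the grid resolution (±30 min is the guaranteed bound).

## Feature vector

With the default 60-minute history at a 5-minute step: 12 glucose lags, 11
first differences, IOB, COB and their rates, time-of-day as (sin, cos) of
2π·minute/1440 (so midnight maps to (0, 1)), day-of-week index, and an
ordinal activity summary (maximum exercise intensity over the last 60 min)
— 31 values. Features are standardised with training-set statistics stored
in the model; zero-variance columns degrade gracefully (unit scale).

## Forecaster

One model per horizon (15/30/45/60 min). Training pairs come from sliding
windows wholly inside gap-free segments, with the target exactly the
horizon ahead. The regression target is the glucose *delta* over the
horizon, which removes the dominant shared scale from the SVR problem.

States are defined by discretising the realised future rate of change at
cut points ±0.1 and ±0.5 mg/dL·min⁻¹ into five trend classes. States with
fewer than 200 training pairs are merged into their nearest class-adjacent
neighbour (richer side wins ties) until all surviving states are viable; a
training set that collapses to one state (e.g. a constant series) skips the
classifier entirely. The gating classifier is a gradient-boosted tree
ensemble (depth 4, 200 rounds, learning rate 0.1, single thread for
determinism); per-state predictors are RBF support-vector regressors
(C = 10, ε = 2 mg/dL — the sensor's own noise scale). Hyperparameters are
fixed and recorded rather than tuned: reproducibility is worth more here
than the last few percent of accuracy. Training subsamples at most 8000
pairs per horizon (seeded, order-preserving) to bound the SVR's quadratic
cost; a week of CGM data sits below this cap, and multi-month histories are
represented by a uniform subsample.

Anchors are clamped to [40, 400]; intermediate 5-minute points come from a
natural cubic spline through (0, current) and the four anchors (natural
boundary conditions avoid endpoint overshoot from an assumed slope).
Training requires 2000 valid CGM points, counted on the raw validated
series, and refuses otherwise; a bundle is stale 14 days after training
(boundary inclusive). Given identical data, seed and configuration,
training and prediction are bit-reproducible.

## No-intervention adjustment

Free-living training data embed the patient's own unrecorded corrections,
so near the range edges a learned model tends to predict recovery that only
happens *because* the patient historically intervened. When (1) the
30-minute OLS trend projects outside [70, 180] mg/dL in the direction of
its slope, (2) the 15-min moving-average slope has not changed sign in the
last 20 minutes (a reversal suggests an unreported event already acting;
slopes below 0.05 mg/dL·min⁻¹ are treated as no direction), and (3) no meal
or insulin was logged in the last 40 minutes, each anchor is blended with
the OLS extrapolation: weight on the linear forecast grows linearly from
0.25 at +15 min to 0.6 at +60 min, because the further out the horizon the
more the learned behaviour reflects past corrections. Exercise and
app-session events do not veto the adjustment. The blend is convex, so the
adjusted anchor always lies between the model and the trend forecast. The
benchmark protocol disables the adjustment, since there it would be
predicting a counterfactual rather than the recorded future.

## Error grids

Clarke zones are evaluated from the published 1987 boundary inequalities;
Parkes (Consensus) zones for the type 1 diabetes grid from the published
boundary-polyline vertex tables, embedded as data and evaluated by
point-in-polygon tests, checked worst zone first. Zone regions other than A
are treated as open sets, so a point exactly on a boundary falls to the
better (earlier-letter) zone — the papers are silent on ties and this
choice is conservative against the method under test. Inputs are clamped to
the 550 mg/dL grid edge; the polygons are closed slightly beyond that edge
so clamped points are classified by region rather than landing on polygon
boundaries. The type 2 Parkes grid is intentionally not implemented (the
intended cohorts are type 1); requesting it raises.

## Glycemic metrics and the stratified comparison

Time in range uses inclusive bounds on [70, 180]. GMI(%) =
3.31 + 0.02392 · mean glucose, reported to two decimals. The risk transform
f(bg) = 1.509·((ln bg)^1.084 − 5.381) (domain 20–600 mg/dL) gives
LBGI/HBGI as means of 10f² over the negative/positive sides; its zero
crossing sits at ≈112.5 mg/dL. Category labels follow the published bands
(HBGI 4.5/9.0; LBGI 1.1/2.5/5.0).

The usage comparison treats patient-days, pooled across patients, as the
unit of analysis. Days are binned by daily app sessions (0, 1–5, 6–10,
>10 — a partition of the non-negative integers); each non-zero bin is
compared to the 0-session bin and to the adjacent smaller bin with
one-sided Welch t-tests (unequal variances are the norm for unequal
day-count bins; whether to pool variances or model per-patient random
effects was an open choice, and pooled day-level Welch is this package's
documented one). Test directions: decrease for mean, SD, GMI, HBGI;
increase for TIR and LBGI (tighter control slightly raises hypoglycemia
exposure). The per-comparison significance level is Bonferroni-corrected,
α = .01/36 (6 metrics × 3 non-zero bins × 2 comparisons), truncated to two
significant digits → .00027. Degenerate zero-variance groups with equal
means report p = 0.5 (the t → 0 limit). Groups with fewer than two days
report the comparison as unavailable (NaN) rather than raising.

## Simulator

The generator is a transparent linear-response difference model, not a
published ODE physiology (no Bergman/Hovorka-style virtual patient is
claimed): per 5-minute step, glucose integrates carb absorption
(carb_sensitivity 3.5 mg/dL·g⁻¹, linear over cad) minus insulin action
(insulin_sensitivity 40 mg/dL·U⁻¹, linear over dia) minus an exercise
drain, plus a circadian oscillation (amplitude 15 mg/dL about a 110 mg/dL
basal), a weak homeostatic pull toward the circadian baseline
(0.005 min⁻¹ — keeps multi-week traces bounded without hiding event
effects), and integrated process noise (SD 1.5 mg/dL per step); the
reported value adds white sensor noise (SD 5 mg/dL) and clamps to
[40, 400]. Meals arrive as a daytime Poisson process (3/day, 20–80 g);
boluses follow meals at carbs/ICR units with ~10 min timing jitter and a
10% chance of being skipped; sensor dropouts (0.5/day, 20–120 min) and
daily session counts (negative-binomial-like, mean 5, spanning all four
usage bins) complete the free-living picture. Event, noise, gap and session
streams are independently spawned from the seed, so deleting an event and
re-running the same seed yields a paired counterfactual.

What passing tests on this simulator do show: the full pipeline learns
genuine event-driven and circadian structure, beats naive baselines, and
degrades with horizon, and every metric behaves correctly on data with
realistic marginal statistics. What they do not show: performance on real
interstitial-sensor data, whose noise is autocorrelated and
calibration-dependent, whose meals are unlogged more often than logged, and
whose physiology is nonlinear and time-varying. Numbers obtained on the
simulator characterise the implementation, not clinical accuracy.

## Problem sizes used in the shipped checks

The forecasting checks train on 45 days of one simulated patient and
evaluate on the following 15 days (every second admissible point); grid
correctness is checked against independently coded geometric oracles on
10⁵ random points per grid plus the full 1-mg/dL lattice; determinism is
checked by training twice on an 8-day patient. These sizes were chosen so
the whole suite exercises every code path at meaningful scale on a single
CPU.

## Known limitations

* Linear on-board kinetics understate the early peak of insulin action;
  the pluggable-curve hook exists but only the linear curve ships.
* The state classifier is trained per horizon; a single shared classifier
  across horizons would halve training cost at some loss of specialisation.
* Basal-rate handling is piecewise-constant bookkeeping only; basal is not
  counted into IOB.
* The stratified comparison is correlational machinery by construction;
  it cannot support causal claims about app usage, and it ignores
  within-patient clustering.
* The Ohio-style XML reader supports the attribute dialect defined by this
  repository's fixtures; files with other attribute conventions need a
  mapping step.
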