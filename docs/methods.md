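# Methods

This note documents the models implemented in `stigsense`, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical conventions.

## Event model and digitization

A stream is an ordered list of binary sensor events `(date, time, sensor,
value, annotation)`. Sensors and activities are digitized to 1-based integer
indices through catalogs; for the CASAS Aruba testbed the fixed mapping is
M001–M031 → 1–31, D001–D004 → 32–35 and the eleven activity classes → 1–11.
ON/OPEN map to 1, OFF/CLOSE to 0; lines whose value is not binary (e.g.
temperature readings) carry no motion information and are skipped with a
warning.

Timestamps are stored as real seconds from midnight of the stream's first
day, so intervals that cross midnight (sleeping, typically) are computed
correctly; the per-day clock is retained for display and round-tripping.
Labeling turns begin/end annotations into per-event activity labels: every
event from a `begin` marker to its matching `end` marker inclusive gets that
activity; everything else is the catch-all `Other_Activity` (underscored so
the whitespace-delimited text format round-trips). Nested or overlapping
spans resolve to the innermost (most recently opened) span with a warning —
a deterministic, auditable rule; an `end` with no open `begin` is an error.

## Offline phase

Four statistics are fitted on annotated training data.

- **SCM** (sensor correlation): entry `(i, j)` is the fraction of length-`ws`
  sliding event windows (stride 1) containing both sensors at least once —
  presence, not multiplicity. It is symmetric with entries in [0, 1].
  `ws` defaults to 15; the windowed-co-occurrence definition needs a window
  scale, 15 events is of the order of a short sub-activity in dense-sensing
  homes, and the value is exposed in configuration rather than hard-coded.
- **SCT** (per-sensor threshold): the minimum SCM value a candidate must
  reach to count as spatially correlated with a target sensor. Two modes:
  an explicit per-sensor *key sensor* map (when floorplan knowledge
  identifies the geographically critical neighbour, whose SCM value becomes
  the threshold), or a rank rule taking the k-th largest off-diagonal entry
  of the sensor's SCM row. The default is rank 2: the strongest partner
  would make the gate nearly unsatisfiable, while the second-strongest
  approximates "the weaker of the nearby same-area sensors" without needing
  a floorplan.
- **MTI** (maximum time interval): for every *ordered* sensor pair observed
  on consecutive events, `mean + 2·std` of the inter-event gaps. Pairs never
  observed in training fall back to a global `mean + 2·std` over all gaps
  rather than failing — an unseen transition should not truncate every
  window to two events.
- **MTS** (maximum time span): sensors cluster into functional areas (a
  configured map); for each area, `mean + 2·std` of the durations of the
  activity instances assigned there. Activities without a configured area
  are assigned by majority vote over the areas of their training events
  (with a warning); areas with no instances use the global fallback.

Standard deviations are the population form (`ddof=0`), with a single
observation contributing zero spread; the estimator is a plug-in description
of the training distribution, not an inference, and the population form is
deterministic for n = 1. `ddof` is configurable.

## Online segmentation

For target event `E_i` the window initializes to `{E_{i−1}, E_i}` (the
immediately preceding event is admitted unconditionally; the very first
stream event yields a singleton). Candidates `E_j` are scanned backward from
`E_{i−2}`; each must pass the sensor check `SCM(S_j, S_i) ≥ SCT(S_i)` (a
sensor always passes against itself) and the time checks
`T_first − T_j ≤ MTI(S_j, S_first)` and `T_i − T_j ≤ MTS(f(S_i))`, both
boundaries inclusive. The first failure ends the scan — the window is a
contiguous run, never a gappy subset. A `max_lookback` cap (default 200
events) bounds the per-event cost when thresholds are degenerate (e.g. SCT
all zeros); it is a latency guard, not part of the statistical model.
Segmentation is causal: the window for target `i` never depends on events
after `i`.

Baselines: fixed-size event windows (last `ws` events) and fixed time
windows (events within `(T_i − Δt, T_i]`, causally restricted).

## Stigmergic features

Times are floored to the `time_step` grid (default 1 s) so the decay
exponents are integers. An activation `[ts, te)` aggregates at window end
`Te` to `I = ((1−ρ)^(Te−te) − (1−ρ)^(Te−ts)) / ρ`, the closed form of the
tick-by-tick superposition of unit deposits with per-step evaporation `ρ`;
`ρ = 0` gives the plain duration. Trigger extraction takes every ON event in
the window in order; its activation ends at the first later OFF of the same
sensor at or before `Te`, else at `Te` (an activation still open at the
window end is capped there — this convention reproduces the documented
demonstration values). The sensor active before the window (searched over
the whole stream history; the first trigger itself if none exists, producing
a self-loop) starts the edge chain; the edge arriving at trigger k carries
that trigger's intensity, repeated edges accumulate by summation, and the
matrix is left unnormalized. Door and motion sensors are treated uniformly.

The duration feature vector `d_k = Σ (te − ts)` over sensor k's triggers is
the order-free baseline; with `ρ = 0`, integer times, and one trigger per
sensor, the DWN's column masses equal the vector's entries.

## Classification and evaluation

The classifier contract is `fit(X, y)` / `predict(X)`; a deep sequence model
can plug in unchanged. The shipped reference is multinomial logistic
regression (scikit-learn, seeded, standardized inputs) chosen so the full
pipeline trains in seconds on one CPU. Training rows are canonically sorted
(label, then feature values) before fitting, so the fit is invariant to
sample order; a single-class training set degenerates to a constant
predictor with a warning.

Cross-validation uses contiguous temporal blocks, not shuffled folds: events
adjacent in time are strongly dependent, and shuffling would leak
near-duplicates across the train/test boundary. Per fold, SCM/SCT/MTI/MTS
are fitted on the training blocks only; windows are segmented causally on
the full stream (test events may appear as unlabeled history context, their
labels never enter fitting). Instance pairing inside MTS fitting is lenient
about markers orphaned by fold boundaries. By default every event is
classified (`stride=1`); a stride is available for quick experiments, but
note that subsampling starves the `S²`-dimensional DWN features of training
examples. Metrics are the per-event confusion matrix, one-vs-rest precision
and recall weighted by true-class support, accuracy (trace over total) and
the weighted F1 (harmonic mean of the weighted precision and recall); a
class never predicted gets precision 0 with a warning so the means stay
defined.

## Synthetic home generator

The generator emulates the statistical structure the method assumes:

- sensors grouped into functional areas; an activity instance is a walk over
  its area's sensors, emitting ON on arrival and OFF after a lognormal dwell
  (positive support, heavy right tail, as dwell times are);
- each activity prefers a cyclic visiting direction over its area's sensors
  (followed with probability 0.7, otherwise a uniform jump) — ADLs are
  directional, and this is precisely the signal trajectory-aware features
  can exploit while duration-only features cannot;
- instance durations are normal with configured mean and spread, and the
  final OFF is clamped to the drawn duration so the emitted durations
  realize the configured distribution (which is what MTS recovery tests
  measure);
- with probability ε (default 0.05) a step fires an out-of-area sensor;
- instances are annotated begin/end on their first/last event; gaps between
  instances are exponential (mean 90 s) with a Poisson number (mean 2) of
  unannotated wander firings that become the catch-all class;
- the schedule is a Markov chain over activities (uniform by default) drawn
  from a dedicated RNG substream, so an independent reimplementation of the
  sampler can replay it — the basis of the twin-sampler test.

The default "mini-home" is 3 areas × 3 sensors with 5 activities
(per-area-identical duration distributions so each area's configured
`mean + 2σ` is well-defined; distinct dwell means and directions so classes
are separable), horizon 100 instances ≈ 3000 events. All draws come from one
seeded generator: a configuration reproduces its stream byte for byte.

What it does **not** emulate: multi-resident interleaving, sensor dropout
and flicker, diurnal schedule structure, heterogeneous sensor ranges, or
any fidelity to a real floorplan. Passing tests on this generator show the
pipeline recovers the structure it posits (area separation in SCM, duration
thresholds, label-pure windows, the benefit of decay and of dynamic
windows); they do not certify accuracy levels on real homes.

## Problem sizes and numerical choices

Tests run the mini-home at horizons 25–200 instances (≈ 800–7000 events) and
the ordering comparisons average five seeded runs at horizon 40 with 5-fold
cross-validation — sizes at which every effect tested is stable and the
whole suite completes in well under a minute. Oracle-equivalence checks use
1000 random cases each. Intensity computations guard the floor-to-grid
division with a 1e−9 epsilon; closed form and explicit sum agree to 1e−12
relative. Serialization stores matrices row-major in JSON with `NaN`
(unobserved MTI pairs) encoded as `null`.

## Known limitations

- The rank-2 SCT default is a heuristic stand-in for floorplan-informed key
  sensors; homes with very different area sizes should supply a key-sensor
  map or another rank.
- The shipped Aruba sensor-to-area map is an approximation of the published
  floorplan and should be replaced for serious use of that dataset.
- The reference classifier is linear; trajectory information beyond what a
  linear readout of the DWN captures (e.g. long-range edge sequences) needs
  a stronger plug-in model.
- `MTI`/`MTS` assume a roughly regular routine; concept drift (a resident's
  schedule changing over months) requires refitting the offline phase.
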