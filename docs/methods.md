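# Methods

This note documents the models and procedures implemented in `aossom`, the
assumptions behind the synthetic-data generator, the numerical choices made
where the underlying method description left the design open, and the known
limitations.

## Signal model and preprocessing

A recording is ten voltage time series, one per MOS sensor, each the
voltage-divider readout `Vout = RL/(RL + Rs)·Vc` of a sensor resistance
`Rs` that declines nonlinearly with gas concentration. Acquisition is
10 Hz for 5 minutes (N = 3000 points per channel); the time grid convention
is `t_i = (i−1)·Δt`, so the first sample sits at t = 0 and "the 20th
second" is exactly sample 201. Recordings are required to hold at least
201 samples so that feature extraction is always well-posed.

Preprocessing applies a one-dimensional running median per channel and then
truncates to the first 5-minute window. Parameters:

* **filter window** — 5 samples (0.5 s) by default, configurable, odd.
  A five-point median removes isolated A/D spike noise at 10 Hz without
  distorting the multi-second transients that carry the features.
* **edge handling** — reflection padding, which avoids boundary bias in
  `Vmax` and `Vt` near t = 0. The filter-then-truncate order is a package
  convention; for interior samples the two orders agree.
* Recordings longer than the window are truncated rather than rejected,
  since only the first 5 minutes are informative for fast measurement.

## Synthetic recordings

No raw soil-headspace recordings were ever published, so the simulator is
the test bed for every downstream stage. It encodes exactly the structural
assumptions the calibration method relies on, with deliberately simple
dynamics:

* **SOM distribution** — truncated normal, mean 23.0, SD 7.4 g/kg on
  [12, 49] g/kg, matching the reference survey's summary statistics.
* **SOM → gas concentration** — a single scalar "effective VOC
  concentration" `c = κ·SOM^γ` (κ = 0.1, γ = 0.8), monotone in SOM. The
  array treats the volatile mixture as a whole, so a scalar abstraction
  is sufficient for pipeline testing.
* **Concentration → resistance** —
  `Rs(t) = R0·(1 + s·c·(1 − e^{−t/τ}))^{−p}`: a nonlinear decline with
  first-order rise dynamics, the qualitative shape of heated-MOS
  transients (fast stabilisation within minutes).
* **Array diversity** — the hardware diversifies the array through ten
  heater voltages; the simulator emulates this with per-sensor
  (R0, s, p, τ): baseline resistance 30→12 kΩ, sensitivity 0.6→2.4,
  decline exponent 0.6→1.5, rise time 120→20 s across the ladder.
* **Noise** — additive Gaussian readout noise, default SD 5 mV (the
  scale of a 10-bit A/D step on a 5 V supply), clipped to [0, Vc].
  Noiseless variants (`noise_sd = 0`) are the reference condition for
  recovery tests.

Reproducibility: every random stream derives from the master seed; each
channel's noise stream is keyed by (seed, sample index, sensor-parameter
fingerprint), so permuting the sensor list permutes channels without
changing their content.

What the simulator does *not* emulate: real VOC mixture chemistry,
humidity/temperature drift, sensor aging, cross-sample carry-over, or any
calibrated SGAS707 physics. Passing recovery tests therefore demonstrates
that the pipeline's inference machinery is correct and self-consistent —
not that the method achieves any particular accuracy on real soils.

## Features and normalisation

`Vmax`, `MDCV`, `RAV`, `Vt` per sensor; 40 features per sample, ordered
sensor-major (S1:Vmax, S1:MDCV, S1:RAV, S1:Vt, S2:Vmax, …), the order
recorded in file headers. Numerical details:

* MDCV is computed as the mean of first differences divided by Δt; it
  equals the telescoped closed form `(D_N − D_1)/((N−1)·Δt)`, which the
  tests use as an exact oracle.
* RAV is the left-rectangle sum `Σ D_i·Δt`, deliberately without a
  trapezoid correction — fidelity to the defining formula.
* The cross-sensor normaliser divides by the n−1 **variance** `S(x)`,
  not its square root, again exactly as defined; consequently normalised
  features scale as 1/c under a common multiplicative rescaling by c.
  The conventional z-score (`normalizer="sd"`) is available because the
  variance divisor is unusual; the default remains the as-defined form.
* All four features are taken from the filtered, truncated window.
* A feature type identical across all ten sensors has zero variance and
  raises a degenerate-feature error naming the feature.

## Kennard–Stone partitioning

Greedy max–min selection under Euclidean distance on the normalised
40-vectors (the feature space is defined post-normalisation, and the
normalised space is what the calibrators see). The training count is
`floor(ratio·n)` — 71 of 102 at the 70/30 ratio. Ties in any distance
comparison break toward the sample whose identifier sorts first, which
makes the partition deterministic and row-order invariant.

## Calibrators

### BPNN

A single-hidden-layer 40–h–1 network, hyperbolic-tangent hidden units,
linear output. Inputs are column-standardised and the target standardised
for training (the 0.001 target MSE is meaningful only on a normalised
scale); predictions are de-standardised. Training is full-batch gradient
back-propagation with Adam steps (learning rate 0.01), stopping at
training MSE ≤ 0.001 or 1000 iterations. The network is implemented
directly in numpy because the selection protocol requires an absolute
target-error stop and per-repeat seeded determinism.

Hidden-size selection: candidates default to 6–16 (the empirical rule
`round(√(n_in + n_out)) + α`, α ∈ 1..10, gives 7–16 for 40 inputs; the
historical experiment used 6–16, and an explicit override replaces the
rule range). Each candidate is trained `repeats` times (default 10) from
seeds spawned deterministically per candidate; min/max/mean training R²
and RMSE are tabulated; the candidate with the largest mean R² wins, ties
to smaller mean RMSE, then smaller h. Diverged repeats (non-finite loss)
are dropped from the means with a warning rather than aborting — the
selection statistic is designed to tolerate bad runs. The training-set R²
defaults to the "printed" form `1 − SSE/Σ(ŷ−ȳ_obs)²` (see Metrics).

### ε-SVR

scikit-learn's SVR backs the fit; the package owns the search protocol.
Kernel `exp(−‖u−v‖²/(2σ²))` (so sklearn's `gamma = 1/(2σ²)`, recorded in
model metadata); ε fixed at the LIBSVM default 0.1. The two-stage search:
coarse log₂ grid over [−20, 20] at step 2 (21×21 cells), then a fine grid
at step 0.25 within ±5 log₂ units of the coarse optimum, clipped to the
coarse range. The fine window is centred on the coarse optimum rather
than hard-coding any historical window, because that narrowing is
data-driven. Both stages score cells by MSECV over the same seeded
five-fold assignment; since the fine grid contains the coarse optimum,
refinement can never score worse. Grid ties resolve to the first cell in
row-major order (smallest log₂C, then log₂σ²).

### PLSR

scikit-learn's `PLSRegression` (NIPALS, centred and unit-variance scaled)
backs the fit; the package owns factor selection. For p = 1..max_factors
(default 15, capped at min(n−1, 40) and at the rank of the centred design,
with a warning when truncated), leave-one-out residuals give RMSECV and
`AIC = N·ln(RSS) + 2p` with the natural logarithm (the standard AIC
convention). The AIC-minimising p is selected, ties to smaller p.
Preprocessing (centring/scaling) is refit inside every leave-one-out fold
— there is no information leakage from the held-out sample.

## Metrics

RMSE, MSECV, RMSECV, two R² forms, RPD, and the A/B/C taxonomy are
implemented exactly as defined, including two idiosyncrasies kept
deliberately:

* the "printed" training R² denominator centres the *predictions* on the
  observed mean (`Σ(ŷ_i − ȳ)²`). This is most likely a typo for the
  conventional `Σ(y_i − ȳ)²`, but it is the form the historical selection
  protocol used, so it is the default for BPNN selection; the
  conventional form is available via `form="conventional"`. The printed
  form is not invariant under affine transformation of predictions — a
  property the tests assert on both forms.
* RPD is computed as `√(Σ(y−ȳ)²/Σ(f−y)²)` (the n factors cancel).

Boundary RPD values classify upward (2.0 → A, 1.4 → B) since the strict
inequalities of the taxonomy leave them undefined; exact predictions give
an infinite-RPD flag (classified A) instead of a crash, so pipelines on
noiseless fixtures complete.

## Pipeline and problem sizes

`run_pipeline` chains all stages under one master seed and ranks models by
validation RPD, then R², then RMSE — RPD drives the taxonomy, so it leads
the ranking. Reports and the comparison table are assembled from the same
`EvaluationReport` objects, so no recomputation drift is possible.

Problem sizes used by the shipped verification runs: the acceptance script
simulates the full 102-sample campaign (10 sensors × 3000 points) with
noiseless sensors and runs all three calibrators with BPNN repeats reduced
to 3; the unit-test pipeline runs use 24–30 samples and 1-minute
recordings. These sizes exercise every code path at full feature
dimensionality.

## Known limitations

* The published absolute performance numbers of the original soil survey
  cannot be reproduced: the raw sensor recordings were never released,
  and the published RMSE and RPD values are mutually inconsistent with
  the RPD definition given the survey's validation SD. The package ships
  them only as a display fixture.
* The simulator's response model is an emulation target, not sensor
  physics; conclusions from simulated campaigns concern the pipeline,
  not field accuracy.
* BPNN training uses Adam rather than a Levenberg–Marquardt optimiser;
  with the target-error stop on standardised data the fitted networks
  reach the stopping criterion well within the iteration budget, but
  per-iteration trajectories differ from classic Levenberg–Marquardt
  toolbox trainers.
* ε is not searched for the SVR (fixed at 0.1), mirroring the protocol's
  use of toolbox defaults.
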