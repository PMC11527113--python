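# Methods

This note records the generative models, estimators, numerical choices and
defaults behind `supercoilfret`, and what the validation suite does and does
not demonstrate.

## Generative models

### Two-state unwinding dynamics

A molecule alternates between a wound (high-FRET) and an unwound (low-FRET)
state with first-order rates k₁ (wound→unwound) and k₋₁ (unwound→wound).
Paths are drawn with the Gillespie algorithm: sojourn times are exponential
in each state's total exit rate, branch choices proportional to branch
rates. One FRET value per sojourn is drawn from the state's Gaussian
emission (default sd 0.02; set to 0 for exactly reproducible levels), and
per-frame channel noise is added on top during rendering.

### Unwinding snapshots (quasi-static approximation)

The time-course experiment samples ~1 s movies at minute-scale intervals,
far below the population relaxation it monitors. The generator therefore
draws each molecule's state *at the sampling instant*: unwound with
probability f(t) = y0 + (plateau − y0)(1 − e^(−k t)), rather than simulating
a full continuous path per molecule. Each molecule contributes ten
donor-excitation FRET values drawn i.i.d. from its population's Gaussian;
ordinal frames 3–7 are the histogram values, which keeps the histogram path
and the trace-rendering path mutually consistent.

Three populations are modeled: a donor-only artifact peak and the two
signal peaks. Defaults (FRET mean, sd): donor-only (0.06, 0.04), unwound
(0.32, 0.06), wound (0.72, 0.07), artifact weight 0.15. No peak positions
or widths are dictated by the assay itself, so these were chosen once for
clear but not artificial separation — the derived classification thresholds
land near 0.17 and 0.52, and the residual overlap misclassifies well under
1% of signal values. Donor-only-component molecules deliberately *pass* the
direct-excitation acceptor filter: they represent acceptors that are
photophysically dark for FRET yet survive the presence check, which is
exactly the artifact population that motivates fitting three components
instead of two. A separate `inactive_acceptor_fraction` population (default
5%) is dark under direct excitation too and is removed by the filter.

### Protein binding movies

Binding events form a renewal process: the wait from the end of one event
to the next arrival is exponential at `k_arrival` (a molecule cannot
re-bind while occupied). Each bound sojourn lasts Exp(k₋₁ + k₂) and exits
to darkness (dissociation) or to the low-FRET sliding clamp with
probability k₂/(k₋₁ + k₂); the clamp leaves the field of view at a single
exit rate (no spatial diffusion model). Default emissions: specific binding
(0.75, 0.05), clamp (0.28, 0.05).

Because the estimator k₁ = events/(molecules × observation time) divides by
wall-clock time while arrivals only accrue during dark intervals, k₁
understates `k_arrival` by the bound-time fraction (≈8% at the default
settings). This mirrors how an event-frequency estimate behaves on real
movies; the waiting-time (k′_on) fit is the unbiased route to the arrival
rate.

### Noise and photophysics

Emission is rendered at a fixed total intensity (default 1000 a.u.) split
between channels by the current FRET value, plus a constant per-channel
background (50 a.u.) and Gaussian channel noise (sd 60 a.u.; a Poisson
shot-noise option exists but Gaussian is the tested default). These values
give a per-frame FRET noise of ~0.05, a typical smTIRF regime; they are
configurable because real signal-to-noise varies between setups.

Photobleaching is exponential in cumulative excitation time (defaults:
donor 0.001 /s, acceptor 0.0005 /s — scavenger-buffer scale, so bleaching
truncates a fraction of a percent of binding events). In the binding
archetype the donor arrives fresh with each event, so its bleach clock
restarts per bound sojourn; DNA-mounted dyes accumulate exposure across the
movie. An unlabeled fraction (default 0) renders molecules dark.

Reproducibility: one master seed; each molecule's stream is spawned from
(seed, molecule index), so datasets are bit-identical for identical
configuration and independent of molecule count changes elsewhere.

## Estimators and numerical choices

### FRET and filtering

E = (I_A − b_A)/((I_A − b_A) + γ(I_D − b_D)) with γ = 1 by default; the
assay reads proximity ratios on a 0–1 scale and no detection-correction
measurement is modeled. Frames with non-positive corrected total intensity
become NaN and are dropped downstream, never errors. Backgrounds are config
constants (no per-trace baseline tracking); donor leakage is not corrected.
The acceptor-presence filter takes the median intensity over the final
direct-excitation segment and requires it to exceed background + threshold
(default threshold: half the single-dye intensity).

### Mixture fitting and thresholds

The three-Gaussian model is fitted to the *binned density* (default bin
width 0.02 FRET units) by nonlinear least squares, initialized at the
10th/50th/90th percentiles with equal weights. Component sds are floored at
0.005 to forbid single-bin spikes. Component intersections are solved in
closed form (quadratic in x after taking logs); when no root lies strictly
between the means — one component dominates the interval — the sd-weighted
midpoint (σ₂μ₁ + σ₁μ₂)/(σ₁ + σ₂) is returned and flagged. Classification
uses strict inequalities, so a value exactly at a threshold falls outside
the window. Both threshold routes are first-class: windows derived from the
fitted mixture (default for new data) and fixed reference windows
(0.14–0.47 and 0.18–0.51) for reproduction runs.

For time courses, thresholds are derived by default from the histogram
pooled over all timepoints — every population is well represented there —
then applied per timepoint; per-timepoint fitting and fixed windows are
options. The association fit weights points by binomial errors
√(f(1−f)/n), uses y0/plateau sanity bounds [−0.2, 1.2] and k > 0, and is
initialized from the first point, last point and 1/median(t). A constant
series returns y0 = plateau with the rate flagged unidentifiable; a
decreasing series fits normally and is flagged by direction. All timepoints
enter the fit; trimming late points is a display option only.

### Idealization and segmentation

The per-trace HMM has Gaussian emissions, is trained by EM (≤500
iterations, log-likelihood tolerance 1e-6) from a deterministic
initialization — means at the 25th/75th percentiles (25/50/75 for three
states), equal variances, uniform start/transition probabilities — and
decoded by Viterbi, so results are reproducible without randomness. States
are relabeled by increasing emission mean. Essentially constant
trajectories short-circuit to a degenerate flag instead of fitting.

Event segmentation thresholds the raw total intensity (threshold must
exceed the summed background) and splits in-event frames at a FRET value
(either supplied or derived from a two-Gaussian fit of the pooled in-event
histogram). A clamp call requires ≥3 consecutive low-FRET frames; shorter
low runs bounded by high frames are absorbed as noise. Events touching
either window edge are censored; the first waiting time of each molecule is
left-truncated and dropped.

### Survival analysis and censoring

For complete dwells the survival curve is the plain empirical 1 − CDF
(survival 1 − i/n at the i-th sorted duration, reaching 0). Excluding
censored sojourns and fitting only complete ones, however, conditions on
completion within the window and length-biases the sample short: on the
default 196 s binding window this inflates the recovered dissociation rate
by ~8% at 0.075 /s and the association rate by ~40%. The pipeline therefore
feeds right-censored dwells and waits into a Kaplan–Meier product-limit
curve (ties: events before censorings), which removes the bias (residual
~1%); the uncensored-only path remains available and its directional bias
is asserted in the test suite. The exponential fit (y = y0 + A1·e^(−kt),
free y0 by default, initialized at A1 = 1, k = 1/mean) runs on either
curve; a 1/mean maximum-likelihood estimator is provided as an independent
cross-check and agrees within 3% on clean data.

Branch decomposition is exact algebra, with standard errors propagated by
the delta method from the fit error on k and the binomial error on the
branch fraction. Rates are in 1/s throughout except the association model
(1/min, with a 1/s conversion in summaries).

## Validation problem sizes

The test suite and the reproduction script run at desk scale on one core:
binding recoveries use 700–800 molecules × 200 s movies per seed (≥2000
uncensored events, three seeds per condition; recovered rates within ~3%
seed-to-seed), snapshot recoveries 5000 molecules × 5 frames per timepoint,
idealization checks 100 traces × 980 frames, and the estimator calibration
50 replicates at n ∈ {100, 1000, 10000}. The whole suite completes in well
under a minute.

## Limitations

* Traces only: no spot detection, drift, or image rendering; acquisition
  artifacts upstream of intensity trajectories are out of scope.
* The Gaussian channel-noise model ignores EMCCD excess noise and
  intensity-dependent shot noise unless the Poisson option is enabled.
* The sliding clamp is a single kinetic state with one exit rate; sliding
  and re-binding dynamics beyond clamp formation are not modeled, matching
  the analysis scope (clamp formation and not beyond).
* Mixed mono/di-labeled protein heterogeneity in event FRET levels is
  supported as an optional two-component emission but is off by default.
* Passing recovery tests shows the estimators are calibrated for data obeying
  these generative assumptions (exponential dwells, Gaussian emissions,
  stationary rates); they do not certify robustness to real-data pathologies
  such as baseline drift, blinking, or non-Markovian dwell distributions.
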