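# Methods

## PRx estimation

ABP and ICP mean series (canonical 1 Hz) are averaged into 10-s bins; a bin
is valid when at least 75% of its samples are present.  PRx is the Pearson
correlation of the binned pairs over right-aligned, half-open windows
`(t_end − 300 s, t_end]`, updated every 10 s.  A window is *missing* (NaN)
when any bin is invalid or either binned channel has zero variance: a flat
channel is exactly the "slow-wave amplitude too low" ambiguity that the
informative-segment classifier addresses, so it is never coerced to 0 or
±1.  All three parameters (averaging interval, window, step) are
configurable; the 10-s/5-min/10-s defaults are the field-standard choice.
Mean CPP/ABP/ICP are co-registered per window from the same bins.

## U-shape fitting

PRx samples are binned against the driver axis (CPP, ABP or ICP) in 5-mmHg
bins aligned to multiples of the width; bins with fewer than 5 samples are
dropped, and a fit requires ≥3 bins spanning ≥10 mmHg.  Bin means are fit
by weighted least squares (weights = bin counts) to a quadratic; R² is the
count-weighted 1 − SSres/SStot.  A fit is valid when it opens upward
(a > 0).  The optimum is the vertex, reported only when it lies inside the
observed bin-center range — extrapolated optima are suppressed.  LLCA/ULCA
are the real roots of a·x² + b·x + (c0 − 0.3), assigned as the lower/upper
crossing around the vertex and likewise restricted to the observed range.
The +0.3 threshold follows the established association of sustained
PRx > 0.3 with fatal outcome and is configurable.  For the ICP axis only
the upper crossing is reported (an "optimal ICP" is not a treatment
target); a downward-opening ICP fit is recorded invalid.

## Segment selection

Each 2-h window is tiled by five half-open 24-min segments; windows slide
by one segment so a fresh decision is available every 24 min.  The base
fitting set is the artifact-free ∧ informative segments.  Remaining
artifact-free (noninformative) segments are visited once, chronologically;
a segment is permanently added iff the refit is valid and its R² strictly
increases.  Artifact-distorted segments never enter.  When the base fit is
impossible (e.g. too few bins), its score is −∞, so the first candidate
that produces a valid fit is accepted.  With no artifact-free informative
segment the window yields no fit and counts as non-yield time.

## Segment classifiers

Two binary RBF-kernel SVMs:

* **Artifact model (X1):** per channel, the pulse amplitude d = sys − dia
  summarized as min, mean, mean |Δd|/Δt, and the fractions of segment time
  with d < 5 and < 10 mmHg (10 features).  Y1 = 1 for artifact-free.
* **Informative model (X2):** per channel, the SD of the mean series after
  centered moving averages of 60/120/180/240 s (truncated edges), plus the
  raw means (10 features).  B-waves (30–120 s periods) survive the short
  filters and are averaged away by the long ones, so the SD decay profile
  encodes slow-wave amplitude.  Y2 = 1 for informative.

Hyperparameters come from the exponential grid: base C = 1 and
γ = 1/(number of features), both scaled by {1/32 … 32} (11×11 = 121 cells),
scored by stratified tenfold cross-validation on pooled accuracy with the
z-scoring refit inside every training fold (no leakage).  Ties break toward
the smallest C, then γ.  Fold assignment orders rows by content before the
seeded shuffle, so results do not depend on row order.  Segments with >50%
missing data have no feature vector: they are excluded from training and
classified artifact-distorted (X1) / noninformative (X2) by policy at
prediction time.  Models persist as versioned JSON (standardization
moments, support vectors, dual coefficients, bias) and the decision
function is reproduced from the stored expansion.

The five management-recognition models are independent binary SVMs on the
window-mean X2 features concatenated with PRx summaries (mean, 10th/90th
percentiles, CPP range); their labels come from the rule-based window
classification below.  The inputs of these models were a genuinely open
design point; this reconstruction is the package's own.

## Window classification and yield

Flags per 2-h window: *critical* — every CPP bin's mean PRx > 0.3 (≥3
bins); *intact* — window mean PRx < 0 (the aggregation statistic is
configurable; the mean is our reading of "PRx < 0"); *cpp/abp-guided* — a
valid fit with an optimum or either limit on that axis; *icp-guided* — an
upper limit on the ICP axis.  The primary situation follows the precedence
critical > intact > cpp > abp > icp > none; all flags are preserved.  The
yield report divides by **all** windows (missing-data windows included), so
each category is a percentage of the full monitoring time; whether the
original bookkeeping was per-window or per-sample was unstated, per-window
is this package's convention.

## Evaluation metrics

Accuracy with a 95% Wilson interval (the CI method was unstated; Wilson is
well-behaved at the extreme imbalances involved), sensitivity/specificity
with artifact-distorted / informative / each situation as the positive
class, Cohen's kappa, rank-based ROC AUC, and the imbalance ratio defined
as majority count / total — the definition that reproduces both of the original
cohort’s printed values (0.945 from 655/11395 and 0.74432 from 8969/3081).

## The simulator

The generator emulates what the method consumes, not full cerebral
hemodynamics:

* **ABP** = baseline + piecewise-linear drift + B-waves + white noise
  (σ = 1 mmHg).  B-waves are per-segment sinusoids, period uniform in
  30–120 s, amplitude 5 mmHg (mid-range for vasogenic slow waves), present
  in a `bwave_on_fraction` (default 0.75, matching the original cohort's
  informative share) of 24-min segments.
* **ICP** = baseline (15 mmHg) + a slow component built by correlation
  injection on 10-s bins: within each 5-min block,
  `icp_slow = ρ_eff·z·s + sqrt(1 − ρ_eff²)·ε·s` with z the standardized
  slow ABP component, ε unit white noise, s = 2 mmHg, and
  `ρ_eff = ρ(CPP)·min(1, s_block/s_ref)` where `s_ref = bwave_amp/√2`.
  At design B-wave amplitude the expected PRx equals the ground-truth
  parabola exactly; without B-waves the measured correlation degrades
  toward noise — the amplitude ambiguity the informative classifier exists
  to resolve.  The gate is this package's extension of the plain mixing
  construction; without it segments lacking slow waves would still carry
  full-strength PRx and segment selection would be inconsequential.
* **Pulse**: sys/dia = mean ± amp/2 with beat-to-beat jitter
  (σ = 1 mmHg) on the amplitude; without jitter a frozen (dropout) line
  would be indistinguishable from a clean one in the pulse features.
* **Artifacts**: Poisson events (default 0.25/h, 60–600 s) of two kinds —
  damped pulse (amplitude decays exponentially to ~1 mmHg, the
  flushed/damped-line signature targeted by the 5/10-mmHg features) and
  dropout (all values frozen).  A segment is labelled artifact-distorted
  when events cover ≥10% of it.
* **CPP sweep** (`sweep_config`): a sawtooth rising 55→105 mmHg over 96 min
  and relaxing back over 24 min, breakpoints aligned to segment boundaries.
  With the period equal to the analysis window, every 2-h window observes
  the full CPP range; a symmetric triangle of longer period leaves
  extreme-centered windows seeing a single flank of the U-shape and was
  rejected for that reason.  The stationary default (no drift, CPP at the
  optimum) is the scene for classifier calibration; the sweep is the scene
  for parameter recovery.

What the generator does **not** emulate: plateau waves, waveform-level
(≥100 Hz) morphology, respiratory modulation, heart-rate variability,
treatment interventions, or amplitude-dependent B-wave spectra.  A green
recovery test therefore establishes the correctness of the analysis chain
on data satisfying the method's own assumptions, not clinical performance.

## Numerical choices and degenerate inputs

Quadratic fits use `numpy.polyfit` with √count weights (equivalent to
count-weighted normal equations, verified to 1e-10 against them); SStot = 0
defines R² = 0.  Constant features are dropped before SVM training and
recorded on the model.  Pearson windows with zero variance are missing, not
0.  Records shorter than one correlation window or analysis window return
empty results with a warning rather than raising.  Bin edges are half-open
`[k·w, (k+1)·w)`; segment and PRx windows use half-open conventions that
tile exactly, and a PRx sample belongs to the segment containing its window
end time.

## Known limitations

* The 1-Hz canonical resolution is a package choice; the source data's
  acquisition rate was unstated.  PRx re-averages to 10-s bins, so nothing
  the method uses is lost.
* The greedy inclusion is single-pass and irrevocable; the original rule's
  ordering and revocability were unstated.
* Whether the original quadratic fits were count-weighted, and their bin
  width, were unstated; 5-mmHg bins with count weighting follow common
  CPPopt practice and are configurable.
* The original headline accuracies and yields were computed on an
  87-patient cohort that is not redistributable; nothing here claims to
  reproduce them, and the in-package checks are parameter-recovery and
  identity tests on the simulator.
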