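# Methods

## The response model

A discrete cognitive event elicits a stereotyped pupil dilation well
described by an Erlang/gamma kernel

    h(t) = t^n · exp(−n·t / t_max),      t ≥ 0,

with shape `n = 10.1` (dimensionless) and peak latency `t_max = 0.93 s`,
the empirical values for attention-driven pupil responses in humans.  The
kernel is analytically unimodal with its maximum exactly at `t_max`.  We
normalise it to unit peak by default (`normalize_peak=True`), so the scale
`s_i` of a pulse is directly millimetres of peak dilation; the kernel's
free vertical scale is otherwise unidentifiable (it is absorbed into the
pulse scales) and normalisation also conditions the least-squares fits.
The kernel is truncated at 5 s, where its amplitude is ~2·10⁻¹² of the
peak, giving finite-support convolutions with negligible error.

The observed diameter is modelled as

    M[t] = b + Σ_i s_i · h(t − t_i),

a static baseline `b` plus a sparse nonnegative pulse train.  Pulse scales
are constrained nonnegative: pulses are dilation-driving processing
events; sustained constrictions are carried by the gap between baseline
and signal, and a short-latency constriction component exists in the
simulator (off by default) to exercise constriction features.

## The online loop (`deconv`)

Processing is strictly causal: the per-frame `step` may read only samples
up to the current frame, which the streaming `DeconvState.push` API
enforces (out-of-order samples raise).

1. **Baseline.**  `choose_baseline` picks a static level: a low percentile
   of the diameter (default 1st), clamped to the observed minimum, or a
   fixed value.  Because this level deliberately sits *below* every
   observation, the quiet-period residual would otherwise be a permanent
   positive offset of roughly the percentile gap (≈2.3 noise SDs), which
   the detector would endlessly "explain" with small spurious pulses.  The
   loop therefore calibrates a tonic offset once, as the median residual
   over the first `warmup_s` (default 0.5 s, assumed event-free), folds it
   into the baseline, and keeps the level static thereafter.  No detection
   happens during the warm-up.
2. **Detection.**  The residual r = Z[t] − M[t] is compared with a
   threshold of `residual_threshold_frac` (default 0.25%) of a reference
   diameter, taken as the recording's median raw diameter (the fraction's
   denominator is otherwise unspecified; the median is robust to the
   pulse-driven upper tail).  A single noisy frame must not trigger: at
   the default conditions the threshold is ≈1 noise SD, so the residual
   must stay super-threshold for `persistence_frames` consecutive frames
   (default 8 ≈ 133 ms).  With Gaussian sample noise this brings the
   false-trigger rate below ~0.01/min while delaying detection by only
   ~130 ms, which the back-projection absorbs.  `persistence_frames=1`
   restores the literal single-frame rule.
3. **Insertion and back-projection.**  On a confirmed detection at time t
   (and at least `refractory_s` = 100 ms after the previous insertion), a
   pulse is proposed at t − `back_offset_s` (default 500 ms).  The
   threshold-crossing time depends on pulse amplitude (the kernel ramp of
   a 0.5-mm pulse crosses a fixed threshold ~60 ms earlier than that of a
   0.2-mm pulse, and both cross ~330–370 ms after onset), so a fixed
   back-projection systematically mis-places weak pulses.  The onset is
   therefore refined by a causal grid search over ±`refine_window_s`
   around the proposal: for each candidate grid onset the best
   nonnegative scale is computed in closed form against the trailing
   window and the candidate with minimal ε wins.  While the newest pulse
   is younger than `refine_age_s` (1.5 s) its onset is re-refined locally
   as more of the response ramp arrives; past the peak the onset is very
   well constrained.  Candidates never come closer than the refractory
   spacing to an existing pulse (if the best candidate would, no pulse is
   added and scales are simply re-fitted), which keeps the pulse list
   refractory-spaced by construction.
4. **Scale optimisation.**  Scales of all pulses whose onset lies inside
   the trailing `opt_window_s` (4 s) window are re-fitted by nonnegative
   least squares (active-set NNLS) against the observed prefix, with the
   baseline and the frozen contribution of older pulses subtracted; a
   ridge-regularised fallback handles singular designs from coincident
   pulses.  Freezing by onset age (rather than by any overlap of the 5-s
   kernel support with the window) avoids re-estimating an old pulse from
   its far tail alone, which is ill-conditioned.  Scales are re-fitted at
   insertion time and then on a 3-frame stride while the newest pulse is
   younger than `settle_age_s` (2 s); after the full peak has been
   observed the scale estimate has settled (SD ≈ σ_noise /‖h‖ ≈ 0.002 mm
   at the default conditions).  Each call can only decrease the windowed
   ε (the previous scales remain feasible).
5. **Finalisation.**  A last scale fit runs, and pulses below
   `min_scale_mm` (default 0.02 mm) are dropped: NNLS fits to pure noise
   produce scales of ~0.002 mm (8 SDs below the floor), which are
   numerical residue, not events.  The final modelled trace equals the
   offline convolution of the final pulse list exactly (self-consistency
   is asserted in the tests to 1e-9).

Determinism: the loop has no random state; rerunning on the same input
and configuration is bit-identical.

## Preprocessing (`preprocess`)

* **Blink detection** is confidence-based (runs of confidence < 0.6 or
  gap-filled samples), padded by 33 ms (two frames at 60 Hz — eyelid
  motion corrupts the diameter slightly before the tracker loses the
  pupil) and merged across gaps < 50 ms.  The detector's thresholds are
  package choices; only the repair method is canonical.
* **Blink repair** fits a cubic spline through four anchor samples, two
  per side at 100 and 200 ms outside the padded interval, and replaces
  only the interior samples.  Through collinear anchors the cubic is the
  straight line, so repairs on trends are exact; intervals at the
  recording edge fall back to a nearest-value hold.
* **Hampel despiking** uses the five-point window (half-window 2), the
  3·1.4826·MAD rule, shrunken windows at the edges, and the limit rule
  that a zero window MAD flags *any* deviation from the window median.
  Statistics are computed from the unmodified input (non-recursive), so
  the filter is deterministic and order-independent.
* **Trial exclusion** drops a trial if gaze eccentricity exceeds 2.8°
  between the first stimulus onset and the response, if a blink interval
  intersects a symmetric 300-ms window around any stimulus onset (the
  conventional reading of "around onset"), or if the trial has no
  response.  Shrinking the gaze limit can only exclude more trials
  (monotonicity is property-tested).
* **Epoching** locks to the nearest grid sample of the event onset
  (≤ 8.3 ms error at 60 Hz, far below the effect timescales) and
  subtracts the mean over the 100 ms (6 samples) before onset.  Epochs
  that would cross the recording edge are dropped and counted; zero
  survivors yield an explicit empty set.

## Epoch statistics (`stats`)

* **Per-sample mixed models.**  At every epoch sample a linear mixed
  model `pupil ~ factor(s) (+ interaction)` with by-participant random
  intercept and slopes for all fixed effects is estimated by REML
  (statsmodels `MixedLM`, lbfgs, warm-started from the neighbouring
  sample).  Factors are binary-coded by sorted level order.  Boundary
  warnings under null data are expected (the slope variance is
  legitimately zero) and are not failures; only exceptions or NaN
  standard errors trigger the random-intercept-only fallback, which is
  flagged per sample.  Significance is the |t| > 2 criterion collected
  into maximal runs of at least 200 ms; no p-values and no further
  multiple-comparison correction are produced, by design.
* **Features** are signed extrema (max dilation, max constriction) and
  earliest-sample latencies within named, configurable windows.
* **Classification** is per-participant logistic regression on
  within-participant z-scored features.  Accuracy is stratified 5-fold
  cross-validated with a recorded seed.  AUC is reported twice, with
  provenance labelled: `auc_insample` (ROC from the model's probabilities
  on all trials) and `auc_cv` (pooled held-out fold probabilities).  The
  in-sample variant is optimistically biased for small trial counts
  (~0.7 under permuted labels at 40 trials × 8 features), so chance-level
  calibration checks use the cross-validated variant, which sits at 0.5
  under label permutation.  A one-sample t-test of participant accuracies
  against 0.5 accompanies the AUCs.

## The synthetic cohort (`simulate`)

`simulate_recording` builds a 60-Hz stream as tonic baseline (4.6 mm for
a dark background, 3.4 mm bright) + Σ s_i·h(t − t_i) + Gaussian noise
(0.01 mm), with blink artifacts carved out (linear collapse to 60% of the
local diameter; confidence set to 0) at 4/min.  Trials follow a dual-task
timeline — fixation 1.1 s → memory array → search array → memory probe →
response — under a 2 × 2 load design.  Pulse scales are 0.25 mm baseline
with a +0.15-mm memory-load effect (encoding and probe pulses) and a
+0.10-mm search-difficulty effect, per-trial SD 0.05 mm, participant
random intercepts and per-factor slopes (SD 0.05 mm each), and 20-ms
onset jitter.  The default cohort is deliberately desk-scale
(8 participants × 40 trials, ~5.4 min of signal each); checks that
specify larger designs (20 × 40 for classifier calibration, 20 × 30 for
the scan validation) construct them explicitly.

`simulate_epoch_cohort` generates epoch-level data directly for the
mixed-model scan: participant intercepts shared by both condition levels,
an optional fixed offset in a window for one level with per-participant
slope deviations, and white trial noise.  Under the null (no offset, no
slope variance) the two levels are exchangeable draws from one
distribution.

`simulate_behavior` draws change-detection behaviour (change present with
probability ½, reports governed by per-level hit/false-alarm rates, so
empirical Cowan's K converges to N·(hit − FA)) and lognormal RTs.

What the simulator does *not* emulate: luminance dynamics and the
pupillary light reflex (a constriction component exists but is off by
default), gaze-dependent foreshortening, tonic drift, or realistic
blink kinematics — blinks only need to exercise the detector's input
contract.  Passing tests therefore demonstrate correctness of the
algorithmic chain under the stated generative model, not performance on
any particular hardware or population.

## Numerical choices and limitations

* Time is seconds everywhere; the grid is uniform to 1e-6 s after
  resampling; duplicated raw timestamps are averaged (order-independent);
  raw clock gaps > 2 samples are interpolated but flagged.
* Event-to-grid alignment is nearest-sample; latency ties break to the
  earliest sample; window bounds are inclusive.
* The static-baseline assumption means slow tonic drift will be absorbed
  into pulse scales; a dynamic baseline is out of scope.
* The 2.8° gaze criterion is applied over one span from the first
  stimulus onset to the response; per-task windows in dual-task trials
  can be approximated by configuring the stimulus event set.
* With a single feature, in-sample AUC is invariant under strictly
  monotone feature transforms; with multiple features logistic regression
  is not scale-free beyond the built-in z-scoring.
* The scan's t-statistics are only as good as REML convergence; at
  variance boundaries two algebraically equivalent codings can differ in
  the third decimal of t, which is why exact-flip properties are tested
  on interior-optimum data.
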