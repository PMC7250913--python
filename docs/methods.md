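# Methods

This note documents the generative models, estimators and numerical
choices in `neurosurv`, and what the synthetic-data validation does and
does not establish about real microscopy data.

## Data model and event coding

An experiment is a hierarchy: plates → wells → imaging fields → neurons.
Wells are the clustering unit (all neurons in a well share transfection
conditions); plates are strata (replicate plates differ in baseline
toxicity).  Fields are imaged at a fixed cadence (default every 24 h)
from t = 0 to the end of follow-up (default 120 h).

A neuron's survival time is the last frame at which it was observed
alive.  A disappearance before the final frame is the death **event**; a
neuron alive at the final frame is **right-censored** there.  (Protocol
descriptions of this assay sometimes swap the words "censored" and
"uncensored" for these two cases; the hazard-ratio directions only make
sense under the standard coding, which is what this package uses.)
Neurons that are never confirmed alive after the first frame have zero
at-risk time and are excluded from record assembly with a logged count.

A consequence of last-alive-frame coding worth knowing: with a horizon
of T hours, deaths occurring in the final inter-frame interval are
recorded at T − Δ, so a landmark (quartile) analysis anchored at T − Δ
has no post-reference events and is undefined.  With the default 120 h
horizon this affects the 96 h landmark; landmark analyses at 24/48/72 h
are unaffected.

## The fate simulator

Death times are drawn from

    h_i(t) = h0(t) · exp( β_g(i) + u_w(i) + γ · z_i(t) )

* `h0`: Weibull baseline with shape k (default 1.3 — a mildly increasing
  hazard producing convex cumulative-hazard curves, as observed in
  chronic neurodegeneration assays) and scale λ in hours (default 150,
  putting control-arm mortality near 50–60% over five days; the
  reporter-linked scenarios use λ = 105, matching the higher mortality
  of a toxic-construct arm).  k = 1 recovers the exponential.
* `β_g`: per-group log hazard ratios relative to an implicit reference.
* `u_w`: optional well-level Gaussian frailty (default sd 0 — enabled
  only for studies of the cluster-robust variance itself).
* `z_i(t)`: the neuron's standardized log reporter level, held constant
  within each inter-frame interval (a piecewise-constant time-varying
  covariate — the simplest form consistent with proportional hazards
  and with covariates being observed only at frames).

Sampling is exact: with `E ~ Exp(1)`, the cumulative hazard is
accumulated interval by interval and inverted analytically inside the
interval where it crosses `E`; neurons whose cumulative hazard at the
horizon stays below `E` are censored.  No discretization error is
introduced beyond the model's own piecewise-constant covariate.

### Reporter trajectories

Red (construct) levels are lognormal across cells (sd 0.4 on the log
scale) and flat in time.  Green (stress reporter) levels are lognormal
with the same dispersion, with an optional group-specific exponential
drift (per-hour log slope), and an anticipatory **surge**: in a
configurable fraction of dying neurons (default 0.6 — "a major
fraction"), the green level ramps up by a factor of 2 (default) over the
last 48 h before death.

The surge creates a chicken-and-egg problem: it is anchored to the death
time, which depends on the hazard, which depends on the reporter.  The
package resolves it by drawing death times from the basal + drift
trajectory only and applying the surge to the *rendered* green
trajectory afterwards.  The surge is therefore an anticipatory marker
(observable in trajectory plots), not a causal input; parameter-recovery
studies of the γ coupling disable it (`surge_fold = 1`) so the
programmed log-linear term is the only reporter–death link, which is the
estimand those studies check.

`gamma_for_quartile_hr(r)` converts a target Q4-vs-Q1 hazard ratio into
γ using the means of a standard normal in its outer quartiles
(±1.2711): γ = ln(r) / 2.5422.

## The imaging model

Living neurons are isotropic Gaussian blobs (σ default 2 px) whose
integrated intensity equals the true trajectory value attenuated by
multiplicative photobleaching (default 2% per frame).  Dead neurons
contribute nothing from the first frame at or after death.  Noise is
Poisson on signal + background (default background 100 counts) plus
Gaussian read noise (default sd 2 counts), applied last.  Blob SNR is
defined as peak amplitude over the background noise sd;
`snr_to_intensity` converts a target SNR into an integrated intensity.
Optional per-frame centroid jitter (`motion_sd`) emulates small cell
movements.  Centers are placed by rejection sampling at a minimum
separation (default 18 px ≈ 9σ): tracked neurons in sparse transfections
are well separated, and the tracker deliberately has no mask-splitting
step (see below), so the simulator does not generate touching somata.

Movies are written as 16-bit multi-page TIFFs, either one file per
channel (`plate{P}_well{W}_field{F}_{red|green}.tif`) or a single
(T, 2, H, W) stack; both dialects are read back transparently.

## The tracker

Per frame (red channel only):

1. Gaussian pre-smoothing, σ = 1 px — a matched-filter denoising step.
2. Threshold.  The default rule is background-anchored:
   `median + max(4 × 1.4826 × MAD, 4% of median)`.  Otsu's method (the
   obvious alternative, offered as `threshold_method="otsu"` with an
   upper-tail re-application guard) has two failure modes on this kind
   of imagery: on frames whose foreground occupies ≪1% of pixels its
   threshold collapses into the background mode, and on noise-free
   frames with heterogeneous cell brightness its valley climbs *into*
   the blob-brightness range and drops the dimmest cells.  The
   background-anchored rule has neither problem and, like Otsu, is
   invariant to intensity rescaling.  A fixed threshold is also
   available.
3. Morphological opening then closing with a 1 px disk; 8-connected
   components; components below `min_area` (default 5 px) dropped;
   unweighted mask centroids.

Fluorescence is measured per object as the mask mean minus a per-image
background (default: median of all non-mask pixels; corner-patch median
available).  The red-channel mask is applied unchanged to the green
channel, and slightly negative background-subtracted means are retained
rather than clipped.

Linking is greedy nearest-centroid within a search radius (default
10 px): at each frame all (track, candidate) pairs within the radius are
sorted by distance (ties broken by lower track id) and assigned so that
no object serves two tracks.  A track with no candidate is declared
absent from that frame on — **no re-acquisition** — so presence is
always a prefix of the frame sequence and the death call is one-way,
like death itself.  Tracks are seeded from user-supplied positions or
from all first-frame objects.

Non-goals inherited by design: no gap-closing, no track splitting or
merging, no drift correction, no neurite segmentation.

## Statistics

**Nelson–Aalen.** H(t) = Σ_{t_i ≤ t} d_i/n_i with variance Σ d_i/n_i²;
subjects censored at an event time count as at risk at that time.
Pointwise 95% CIs are linear (H ± 1.96·√var) clipped at zero.

**Cox model.** The stratified log partial likelihood (separate baseline
per plate, common β) is maximised by Newton–Raphson with step-halving,
to a gradient 2-norm of 1e-8 (max 100 iterations).  Covariates are
centered for conditioning; the linear predictor is shifted by its
maximum before exponentiation (the partial likelihood is invariant to
both).  Ties: Breslow by default — event times on a 24 h grid are
heavily tied, and Breslow admits an independent brute-force oracle —
with Efron available.  Delayed entry (left truncation) restricts each
stratum's risk set to `entry < t ≤ time`.

Monotone likelihoods (perfect separation) are flagged: a diverging
coefficient (|β| > 25 during iteration, or > 15 at a vanishing-gradient
plateau) marks the fit non-converged with a diagnostic message rather
than returning a silently huge estimate.

**Cluster-robust variance.** The sandwich `I⁻¹ (Σ_g u_g u_gᵀ) I⁻¹`
aggregates score residuals within wells, multiplied by the finite-sample
factor `G/(G−1) · (N−1)/(N−p)` — the convention of Stata's
`vce(cluster)`, the software environment in which this class of analysis
is usually run.  With singleton clusters this reduces (up to the factor)
to the unclustered score-residual sandwich.  Score and Schoenfeld
residuals use Breslow risk-set weighting in all cases; with untied data
the ties conventions coincide, and the pipeline default is Breslow
throughout.  Expect robust-CI coverage a little below nominal with few
wells: measured 0.91–0.92 at 16 wells against a nominal 0.95 over 200
simulated replicates.

**Proportional-hazards diagnostics.** The Grambsch–Therneau score test
correlates Schoenfeld residuals with a transform of event time
(identity by default, Kaplan–Meier available; the KM curve is evaluated
right-continuously at the event time), using the average-information
approximation V(t) ≈ I/d.  Per-covariate χ²(1) statistics and a global
χ²(p) are reported.  The statistics agree with the independent
implementation in lifelines to 1e-6 on untied data.

**Reporter normalization.** Green levels are divided by the control
group's mean at a reference time (so the control mean maps to 1.0),
making trajectories comparable across constructs and days.

**Quartile analysis.** Neurons alive and measured at the landmark are
binned at the empirical 25/50/75 percentiles (linear interpolation);
boundary ties go to the lower quartile; a degenerate distribution puts
everyone in Q1 with a warning.  The hazard model uses Q2–Q4 indicators
(Q1 reference, HR ≡ 1), clustered by well and stratified by plate, with
follow-up left-truncated at the landmark — without truncation a neuron
would accrue risk time before its covariate existed (immortal-time
bias).  Optionally a group indicator is added (two-step adjustment).
Quartiles are pooled across groups by default, which is what makes the
group-adjusted model meaningful.

A monotone dose-response across quartiles is assessed by the standard
test for trend: a Cox fit on the ordinal quartile score (1–4), positive
and significant.  The stricter event — all four HR point estimates in
increasing order — is noisy at n ≈ 1000 (adjacent-quartile contrasts of
~0.18 on the log scale carry SEs of ~0.11) and holds in only ~86% of
replicates even when the programmed effect is perfectly monotone; the
trend test detects it in ~100%.  Validation asserts the trend test and
reports the strict ordering rate.

## What the validation shows — problem sizes

The test suite and `scripts/acceptance.py` measure, at fixed seeds:

* **Cox oracle equivalence** — the Newton fit equals a 1e-4-step grid
  maximization of the Breslow log partial likelihood on an exhaustive
  family of 5-record datasets plus random datasets up to 8 records
  (flat-likelihood degeneracies excluded; boundary maxima are the
  separation cases, which are flagged, not estimated).
* **Nelson–Aalen hand check** — deaths at 24 and 48 h with a censoring
  at 72 h give H(24) = 1/3, H(48) = 5/6.
* **Group-HR recovery** — 2 plates × 8 wells × 1008 neurons, true
  HR 1.5, 200 replicates: mean estimated HR within 5% (measured ≈ 0.3%
  off), robust-CI coverage within [0.90, 0.98].
* **Quartile recovery** — programmed Q4-vs-Q1 HR 2.0 at n = 1008, 200
  replicates: mean Q4 HR within 10% (measured ≈ 1–2% off), positive
  trend detected in ≥ 90% (measured 100%); with γ = 0 quartile effects
  are ≈ 5% false-positive calibrated.
* **Schoenfeld calibration** — PH-true n = 504, 200 replicates: type-I
  error within [0.02, 0.08]; a programmed hazard crossing (log-HR +0.8
  → −0.8 at 60 h, n = 500) is detected with power ≥ 0.8 (measured
  ≈ 0.99).
* **Tracking fidelity** — 15 fields × 6 frames × 10 neurons: fate
  recovery 100% on noise-free renders and ≥ 99% (measured 100%) at
  uniform blob SNR 10 with 1 px jitter; green estimates on noise-free
  renders match truth through the mask aperture within 5%.
* **End-to-end equivalence** — group-model β from tracked noise-free
  movies equals β from the simulator's fate tables to 1e-6 (measured 0).

The SNR-10 fidelity condition renders all cells at the stated SNR
(near-uniform brightness, no bleaching); under the default lognormal
brightness spread, the dimmest cells sit at effective SNR 3–4 and fate
accuracy is governed by them, not by the nominal SNR.

## What the synthetic data does not emulate

Real neurons have neurites, irregular somata and debris; dying cells
fragment rather than vanish between frames; cultures drift in focus and
stage position; background is vignetted, not flat; and real reporter
dynamics are richer than lognormal-basal + drift + surge.  Passing the
validation therefore establishes the *correctness of the computations*
— segmentation geometry, linking logic, estimator algebra, calibration
of the tests — not robustness to these real-data complications.  The
death call in particular replaces human frame-comparison with the
no-re-acquisition rule; on real data its disagreement rate with a human
scorer is unknown and worth measuring before trusting absolute survival
times.

## Known limitations

* Cluster-robust coverage runs ~3 points under nominal with 16 wells;
  with fewer wells a wild-cluster bootstrap would be preferable.
* Breslow ties are slightly conservative with very heavy grid ties
  (many deaths per frame at small n); Efron is available but its robust
  variance reuses Breslow-weighted residuals.
* The 96 h landmark is structurally empty at a 120 h horizon (see event
  coding); extend follow-up to use it.
* Segmentation assumes isolated cells; touching somata are merged, not
  split.
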