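# Methods

## Scope and data model

`qmripd` analyzes multi-visit quantitative MRI of solid tumors under a
stroma-modifying treatment. Inputs are NIfTI volumes referenced by a study
manifest (subject, tumor, visit, series kind, path, acquisition metadata)
plus integer-labelled masks for tumors, a reference tissue and an artery.
Every fitting stage produces a `ParameterMap`: a voxel grid of values in
stated units together with a validity mask; all downstream statistics
(VOI medians, pixel tables) consume valid voxels only, except where noted
below.

The pipeline stages run in dependency order per subject and visit: ADC
from DWI replicates, T1 from the VFA series, signal-to-concentration,
AIF extraction, iAUC, extended Tofts, then study-level statistics
(repeatability coefficients, VOI responder labels, baseline-threshold
rules, pixel-level decision-tree analysis). Missing series skip their
stage with a machine-readable exclusion record rather than aborting — the
behaviour multi-site trial data demand.

## ADC

Mono-exponential decay S(b) = S₀·exp(−b·ADC). With the two-point protocol
(b = 0 and 450 s/mm²) the estimate is the closed-form log ratio; with more
b-values, ordinary least squares on log signals. Design choices:

* Voxels with any non-positive signal are invalid (log undefined).
* Negative fitted ADC (signal rising with b — pure noise) is *returned*
  but flagged invalid, never clipped: truncating a noise distribution
  one-sidedly would bias VOI medians.
* Replicates are fitted independently and averaged voxelwise; a voxel is
  valid in the average if valid in at least one replicate.
* Series whose b-values deviate from the configured protocol set are
  excluded at the manifest level (`allowed_b_values`), with an exclusion
  record.

## T1 (variable flip angle)

SPGR steady state S(α) = M₀ sin α (1−E₁)/(1−cos α E₁), E₁ = exp(−TR/T1).
The per-voxel fit is seeded by the DESPOT1 linearization (S/sin α against
S/tan α; the slope is E₁) and refined by a vectorized golden-section
search over T1 ∈ [0.05, 4] s with M₀ profiled out analytically, which is
deterministic and immune to start-point effects.

At the emulated protocol — TR ≈ 3 ms with flip angles 15–60°, far above
the Ernst angle of long-T1 tissues — T1 is weakly identified per voxel:
a 1 % perturbation of a signal ratio moves the fitted T1 by roughly 13 %.
Three consequences shape the implementation:

* **Bound-clamped voxels stay valid.** A fit pinned at the T1 bound says
  "at least this long", which is rank-correct inside a median; censoring
  such voxels was measured (on uniform-truth phantoms at 2 % noise) to
  bias VOI medians by about −5 %, while retaining the clamped value keeps
  the bias near −1.5 %. Clamped voxels are recorded in
  `T1FitResult.at_bound`.
* **Degeneracy is flagged by identifiability, not by the seed.** Voxels
  whose fitted E₁ falls below 10⁻³ (the TR ≫ T1 regime, where the signal
  no longer depends on T1) are invalid; a failed DESPOT1 seed alone is
  not disqualifying because the bounded refinement searches the full
  range regardless.
* **Spatial smoothness acts on R1 = 1/T1**, where the signal model is
  closer to linear. With weight λ > 0 the voxelwise R1 map is updated by
  solving the sparse quadratic problem min ‖r − r_fit‖² + λ‖L r‖² (L the
  3-D grid Laplacian with replicate boundaries), after which M₀ is
  re-profiled against the smoothed T1. Heavy smoothing converges to a
  harmonic-type mean of T1, so exact mean preservation holds only for
  small voxel scatter — the shift is of order (scatter/mean)².

Two acquisition-defect corrections are available: a single global
flip-angle scale κ ∈ [0.5, 1.5] (true angle = κ × nominal), estimated by
minimizing the total profiled residual over a coarse grid plus bounded
refinement and requiring ≥ 3 distinct angles (with two, κ and T1 trade
off exactly); and per-volume intensity scales anchored to a reference
region of known T1 (defaults at 1.5 T: blood 1.4 s, liver 0.58 s, muscle
0.85 s), with the first volume's scale fixed to 1.

## DCE

**Concentration.** M₀ per voxel is implied by the mean pre-injection
signal and the pre-contrast T1 map (or a configured reference T1 when
pre-contrast mapping is missing); each frame's signal is then inverted
through the SPGR equation to T1(t) and
C(t) = (1/T1(t) − 1/T1_pre)/r₁. Default relaxivity r₁ = 4.5 s⁻¹mM⁻¹
(typical 1.5 T gadolinium chelate), configurable. Frames whose signal
falls outside the attainable SPGR range are flagged per voxel.

**AIF.** The mean concentration curve over arterial voxels; bolus arrival
is the first frame exceeding the pre-injection mean by
max(5 × baseline SD, 10 % of the peak excursion). Without an artery mask
the biexponential population bolus
C_p(t) = D·Σᵢ aᵢ e^{−mᵢ(t−t₀)} is used, with a = (3.99, 4.78) kg/L,
m = (0.144, 0.0111) min⁻¹ and dose D = 0.1 mmol/kg.

**iAUC.** Trapezoidal integral of C(t) over the 90 s following bolus
arrival (anchor configurable to the injection frame), with linear
interpolation at the window end. Negative noise excursions are integrated
as-is.

**Extended Tofts.** C_t(t) = v_p C_p(t) + k^trans ∫₀ᵗ C_p(τ)
e^{−(k^trans/v_e)(t−τ)} dτ. The convolution is evaluated by the
exponential-kernel scheme exact for piecewise-linear C_p — as a
closed-form decay matrix for single-voxel calls and as a sequential
recursion for voxel arrays; the two agree bitwise. Fitting is bounded
nonlinear least squares (k^trans ∈ [0, 5] min⁻¹, v_e ∈ [10⁻³, 1],
v_p ∈ [0, 0.5]) from three starts spanning low/medium/high exchange, with
an analytic Jacobian; the best residual wins, so results are independent
of start order and voxel execution order. All-zero curves return the
degenerate (0, v_e-floor, 0) marked invalid; fits pinned at informative
bounds are flagged (k^trans = 0 and v_p = 0 are legitimate physiology and
are not).

## Repeatability

σ_w² is the pooled one-way within-subject variance
Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)² / Σᵢ (nᵢ − 1) — covering both replicate pairs and
triplicates — and RC = 2.77 √σ_w² (2.77 = 1.96·√2): for gaussian
measurement error, ±RC brackets ~95 % of test-retest differences. Per
tumor, the ADC RC comes from that tumor's baseline replicates when
available, else the whole-data (pooled) RC, else the shipped default
0.8 × 10⁻³ mm²/s. The pixel-level analogue samples an equal number of
masked pixels per subject (the smallest subject's count, seeded, without
replacement) before pooling, so large tumors do not dominate; the shipped
group pixelwise ADC RC is 1.4 × 10⁻³ mm²/s. Parameters without replicate
acquisitions use literature RCs: T1 0.27 s (absolute), iAUC ±32 %
(relative to baseline), k^trans −45 %/+83 % (relative, asymmetric),
v_e 0.076, v_p 0.0062 (absolute). Relative RCs are anchored to the
baseline value — the only defensible reference.

## Response classification

VOI medians are taken over valid masked voxels; a tumor-visit with fewer
than 5 valid voxels is excluded with a logged reason. A parameter change
(day 1 − baseline; absolute or fractional per the RC mode) beyond the
directional bound — below −RC for ADC and T1, above +RC for iAUC,
k^trans, v_e, v_p — labels the tumor a pharmacodynamic responder (P).
Later visits are labelled too but only day 1 feeds threshold learning.

Baseline-threshold rules are learned by exhaustive search over midpoints
of consecutive distinct baseline values (plus one candidate beyond each
extreme), maximizing balanced accuracy; ties break toward higher
specificity, then smaller absolute threshold. Significance is the exact
two-sided McNemar test on discordant counts, p = min(1, 2·P(X ≤ min(b, c)))
with X ~ Binomial(b+c, ½); b + c = 0 gives p = 1 by convention.

The pixel-level analysis builds one row per tumor voxel with complete
baseline and day-1 values of all six parameters, labels a pixel a
p-responder when any parameter beats its directional RC, and trains a
Gini CART tree (default depth 1 — the selected model in this setting is a
single v_e split) on baseline values. Per training iteration, each
subject contributes floor(0.85 × smallest-tumor pixel count) pixels drawn
without replacement; the pooled draw is down-sampled to equal class
counts; validation is per subject on the undrawn pixels and the iteration
with the best mean validation BA wins. Class balancing at the pooled
level (rather than within subject) is the default; evaluation is
leave-one-patient-out, with folds whose held-out pixels contain a single
class reported as missing and excluded from the mean.

## The phantom generator

The generator emulates the trial protocol so the full chain can be tested
against ground truth: a ≥ 16×16×4 voxel grid (default 32×32×8 at
1.5×1.5×8 mm) with ellipsoidal tumor/reference/artery regions; per-region
tissue truth (ADC, T1, k^trans, v_e, v_p, M₀) within physical bounds;
smooth intra-region heterogeneity (unit-variance gaussian random field at
~3-voxel correlation length, scaled by a per-parameter relative SD,
clipped to bounds with a warning); a multiplicative day-1 treatment
effect (default ADC×0.8, T1×0.8, k^trans×1.8, v_e×1.4, v_p×1.5) that
decays over visits (baseline/day 1/visit 2/last at remaining fractions
0/1.0/0.4/0.1) and may be gated on a baseline predicate (e.g.
v_e < 0.39), in which case exactly the gated voxels change. Forward
simulators produce: DWI at b = 0/450 s/mm² in 3 replicates; VFA SPGR at
15/23/30/60°, TR 3 ms, with optional flip-angle scale and per-volume
gains; and a 48-frame DCE series at 8 s spacing with injection after
frame 8, tissue kinetics from the extended Tofts forward model, artery
voxels carrying the AIF itself. Noise is gaussian (Rician optional) with
SD = `sigma_rel` × the reference-region signal of the relevant series —
for VFA that is the observed T1w signal at the lowest flip angle, not M₀,
since at ms-scale TR the SPGR signal is a small fraction of M₀. Default
`sigma_rel` = 0.02. All randomness flows from the spec seed,
deterministically split per series; identical spec and seed give
bit-identical outputs.

What the phantom does *not* emulate — and hence what passing tests do not
establish about real data: scanner artifacts (motion, ghosting, B0/B1
field maps beyond a scalar κ), k-space effects, mis-registration between
visits (grids are aligned by construction; co-registration is assumed
upstream), partial-volume mixtures at region boundaries, and non-gaussian
physiological variability between visits.

## Numerical choices and problem sizes

* T1 golden-section refinement: 60 iterations over [0.05, 4] s
  (bracket width < 10⁻⁹ s); κ search: 51-point grid + bounded refinement
  to 10⁻⁵.
* Tofts fits: `scipy.optimize.least_squares` (TRF) with xtol = ftol =
  10⁻¹⁰ and the analytic Jacobian; small-exponent branches switch to
  series expansions below kep·Δt = 10⁻⁶ to avoid cancellation.
* The arrival detector requires ≥ 4 pre-peak frames; iAUC integrates to
  the last frame with a warning when the series ends inside the window.
* Test and acceptance studies use 16×16×4 grids with two tumors
  (~60–240 voxels each), two visits and 48 DCE frames, and 100-voxel /
  100-seed batches for noisy-recovery statistics; these sizes make the
  voxelwise Tofts fitting (the dominant cost) complete in seconds per
  subject while leaving every statistical property measurable.
* End-to-end determinism: re-running the pipeline with the same manifest,
  configuration and seeds reproduces measurements and labels exactly.

## Known limitations

* No IVIM/kurtosis diffusion models, no Rician-bias-corrected ADC.
* No inversion-recovery T1, no voxelwise B1 maps (κ is a single scalar).
* No 2CXM/shutter-speed kinetics, no AIF deconvolution, no temporal
  interpolation of dropped frames.
* Image co-registration is out of scope; real data must arrive aligned.
* The decision-tree stage does not reproduce Weka J48 pruning semantics;
  the split criterion (Gini) is a declared choice.
* Confidence intervals on RC and inter-scanner reproducibility are not
  implemented.
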