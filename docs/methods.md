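# Methods

## Scope and validation strategy

The package implements a muscle-DTI analysis chain — diffusion tensor
estimation, fascicle tractography, architecture metrics, and interlimb
deficit statistics — for bilateral two-group studies (hemiparetic
cerebral palsy vs. typically developing controls).  Clinical source
data of this kind are not redistributable, so the package validates by
**parameter recovery**: synthetic generators with analytically known
truth stand in for acquisition, and every downstream stage is judged by
how well it recovers what the generator injected.  Passing these checks
demonstrates that the estimators are correct and calibrated under the
stated generative assumptions; it does not certify performance on real
scanner data, whose artifacts (motion, eddy currents, susceptibility,
fat signal, partial volume) the generators deliberately omit.

## Phantom model

The muscle phantom is a unipennate slab: a rectangular muscle
(default 60 × 20 mm in-plane, 13 mm deep) whose top face is the
aponeurosis and whose fibers are straight lines in the x–z plane at the
pennation angle θ to that face.  This gives closed forms for every
architecture outcome: fascicle length = thickness/sin θ (slab x-extent
at θ = 0), volume = the analytic slab volume (extents are voxel
multiples by default, making rasterization exact), and
PCSA = volume·cos θ / length.  Default tensor eigenvalues are
(2.1, 1.6, 1.6)×10⁻³ mm²/s — literature-typical for skeletal muscle,
config-exposed since the modelled study reports no numeric
diffusivities — with the principal eigenvector along the fiber.
Voxels outside the muscle carry an isotropic tensor at S0/10, so that
tracks are stopped by the mask with a realistic signal drop behind it.
Bipennate or curved-fiber geometry is out of scope.

The acquisition model mirrors a standard muscle protocol: 10 b = 0
volumes plus 12 directions at b = 400 s/mm² (three magnitude averages
per direction) on 1.25 × 1.25 × 6.5 mm³ voxels.  The 12 directions were
fixed once by electrostatic-repulsion optimization (minimum angular
separation 38.9°).  Noise is Rician, applied per average with
σ = S0/SNR and averaged on noisy magnitudes, as a scanner does; the
b = 0 mean therefore sits above S0 at low SNR (the noise floor), a bias
the tests assert rather than remove.

## Tensor estimation

Two-pass weighted linear least squares on the log signal: an OLS pass
initialises ln S0 and the six tensor components, one reweighting pass
with weights equal to the squared predicted signal corrects the
log-transform heteroscedasticity.  The estimator is deterministic, has
no iteration-count ambiguity, and equals the exact inverse on noiseless
data; on 100 random SPD tensors it agrees with an independent
Levenberg–Marquardt fit in the signal domain to ~10⁻¹⁴ relative.
Voxels with non-positive or non-finite signal are flagged unusable
(`fit_ok = False`) and excluded from tracking and from whole-volume
averages — the count is logged.  Non-positive-definite fits keep their
tensor but have eigenvalues clamped at zero for scalar computation;
FA of the all-zero triple is defined as 0.  No per-voxel outlier
rejection is applied.  Whole-volume scalars are unweighted means over
usable muscle voxels; no further volume normalization is applied.

## Tractography

Seeds at every muscle-voxel center; bidirectional propagation with step
0.5 mm; termination on mask exit, on a turn exceeding the cap (default
90°), on FA below the floor (default 0), or at 2000 steps (1 m guard).
Design choices:

* **Orientation lookup is nearest-voxel**, not interpolated:
  eigenvector fields are sign-ambiguous, and interpolating across
  strongly anisotropic 6.5 mm slices creates artifacts.  Voxel
  ownership is half-open; world coordinates go through the NIfTI RAS
  affine.
* **Antipodal symmetry** is resolved by aligning each sampled
  orientation with the previous step.  A consequence worth stating:
  the effective turn between steps never exceeds 90°, so a turning cap
  of exactly 90° can only fire on a perfectly orthogonal field change;
  the cap becomes an active constraint below 90°.
* **Terminal clipping**: when a step would exit the mask, the last
  in-mask point on the segment is appended (bisection to 10⁻⁶ mm), so
  track length is not quantized by the step at the boundary.  All other
  inter-point spacings equal the step exactly.
* **Probabilistic mode** replaces the principal eigenvector by a draw
  from a Watson-type axial distribution (density ∝ exp(κ(μ·x)²))
  with configurable concentration κ; κ = ∞ is the deterministic mode
  used for validation.  This is a parameterized stand-in for posterior
  orientation sampling — the package does not estimate orientation
  posteriors from the data — and is sampled by rejection with a
  truncated-exponential envelope (acceptance → 1/2 at large κ).
  Fixed seeds make tracking bit-reproducible.

Filtering: boundary contact (an endpoint within one voxel diagonal of
a boundary voxel) is mandatory; optional length bounds; and an
optional endpoint-pair rule requiring one endpoint on the aponeurosis
and the other on the deep surface.  Endpoint surface assignment uses
the *exit face*: the endpoint's nearest boundary voxel is found, the
voxel face the endpoint is closest to (in voxel-normalized coordinates)
is identified, and the face must both carry the label and point along
the label's outward normal.  This distinguishes lateral exits from
genuine aponeurosis/deep transits even in slabs only two voxels deep,
where any point is within a voxel diagonal of both faces.  Each
rejected tract records its first failed rule.  The exact anatomical
constraint set of a given study is config-driven (`FilterConstraints`);
in phantom validation the endpoint-pair rule is enabled for pennate
slabs and disabled at θ = 0, where fibers run parallel to the
aponeurosis and by construction never reach it.

## Architecture metrics

Fascicle length is polyline arc length (not chord).  Pennation is the
angle between the fascicle's end-to-end chord and the local aponeurosis
tangent plane — a principal-plane fit over labelled voxels within
10 mm of the fascicle's aponeurosis-side endpoint (nearest three voxels
if the neighborhood is too sparse).  The chord is robust to step-level
jitter; a mean-tangent variant is exposed for comparison.  PCSA uses
the summary statistic μ over valid fascicles; μ defaults to the
arithmetic mean with median and histogram-mode (Freedman–Diaconis
bins) variants mirroring the usual robustness check.  Cross-muscle
aggregation is the volume-weighted mean of each outcome.

## Cohort generator

One baseline per participant and outcome on the reference
(nonparetic/dominant) arm; the other arm is baseline × (1 − deficit),
with the fractional deficit drawn per participant from the group's
normal distribution truncated below 1 (the weaker arm stays positive,
keeping percent-deficit denominators valid).  Default conditions are
the modelled effect structure: volume deficits 27% (HCP) and 4.5% (TD)
with 10 pp spread; MD deficit 9.3% (HCP) and 0% (TD) with 5 pp spread;
baselines 30 000 mm³ (CV 0.25) and 1.767×10⁻³ mm²/s (CV 0.05).  The
grip-strength percent deficit is generated linearly,
PD_grip = 1.27·PD_volume + 0.843·PD_MD + ε, with ε ~ N(0, 17.5 pp);
the residual spread was set analytically so the two predictors jointly
explain ≈ 0.6 of the grip-deficit variance at these effect sizes, and
the simulation studies confirm a mean marginal r² of ≈ 0.61.  Ages are
uniform on 6–40 years and sexes ~60% female, matching the modelled
cohort's composition.

## Statistics

* **Percent deficit**: (reference − other)/reference × 100; positive
  when the paretic/nondominant arm is smaller; scale-invariant.
* **Interlimb models**: `value ~ group × arm` per outcome, REML mixed
  models (statsmodels MixedLM) with crossed random intercepts for
  integer age-year bin and sex.  Because arms are paired within
  participants, the default adds a per-participant random intercept; a
  switch reproduces the literal age-and-sex-only specification.
  Per-group interlimb contrasts (other − reference) are reported with
  t-based p-values, df = n − rank(X) — a small-sample improvement over
  the Wald normal.  Under the null the HCP contrast's type-I error is
  0.03–0.05 across 500 simulated cohorts at α = 0.05.
* **Degenerate data**: when the mixed fit is singular (zero residual
  variance or a non-PD covariance) the fit falls back to ordinary least
  squares with zero variance components and is flagged — this keeps the
  zero-noise limit exact instead of erroring.
* **Correlations**: Pearson r between each outcome's PD and the
  grip-strength PD, pooling both groups; zero-variance inputs yield
  NaN-marked results.
* **Integrated model**: `PD_grip ~ PD_volume + PD_MD` with the same
  random-effect structure; reported r² is the marginal (fixed-effects)
  variance fraction var(Xβ)/(var(Xβ) + Σσ²_RE + σ²), matching the
  single- vs two-predictor explanatory-power comparison.  Predictor
  collinearity |r| > 0.999 is flagged, not rejected.  With the
  residual switched off the model recovers the generator weights to
  10⁻⁶ and r² = 1; at study size (n = 30) the 95% CIs cover the
  generator weights in ≈ 92–94% of simulations — the familiar mild
  small-sample anticonservatism of Wald-type mixed-model intervals.
* **Demographics**: ages parsed from "Y y M m" strings (months/12),
  Welch t-test for age, chi-squared for sex; α = 0.05 two-sided
  throughout, no multiple-testing correction.

## Numerical and I/O choices

NIfTI-1 (RAS affine) for volumes; FSL-dialect bval/bvec (3 × N, with
N × 3 auto-detected; non-unit vectors renormalized with a warning,
zero vectors at b > 0 rejected); TrackVis .trk (float32 world-mm) plus
an exact-precision TSV for tractograms; TSV/JSON elsewhere, with
round-trip float parsing.  A single global seed derives per-stage seeds
by hashing the stage name, so stages rerun in isolation reproduce the
full run; two runs with the same config are byte-identical, checksummed
in the run manifest.

## Problem sizes

Validation uses three phantom angles (0°, 15°, 30°) on a
48 × 16 × 2-voxel muscle grid (1536 seeds per phantom), the SNR grid
{∞, 50, 30, 20}, 500 null cohorts for calibration, 100 cohorts for
deficit recovery and 200 for CI coverage — sizes at which the Monte
Carlo error is well below the acceptance margins while the full
validation completes in minutes on one CPU.

## Known limitations

* The phantom's uniform straight-fiber field cannot probe curved or
  crossing architecture, partial-volume boundaries, or fat
  infiltration.
* Probabilistic tracking perturbs the fitted principal eigenvector; it
  does not propagate per-voxel posterior uncertainty from the data.
* The aponeurosis labels are inputs (the phantom provides them);
  automatic aponeurosis identification is not implemented.
* Mixed-model inference uses Wald-type CIs with a t reference;
  fully corrected small-sample df (Kenward–Roger style) is not
  available in the underlying library, so CI coverage at n = 30 sits
  slightly below nominal.
* At θ = 0 the endpoint-pair filter is inapplicable (fibers never meet
  the aponeurosis); length validation there relies on boundary contact
  alone.
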