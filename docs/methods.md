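# Methods

This note documents the models, numerical choices, and synthetic-data
design behind nephrokit, and what the test suite does and does not
establish about real data.

## One-tissue compartment PET model

The tissue compartment obeys dC_t/dt = K₁·C_a(t) − k₂·C_t(t) and the
measured signal is C_PET = (1 − v_b)·C_t + v_b·C_a. Frame values are
time-averages of C_PET over each frame interval.

**Exact forward model.** The input function is piecewise linear between
its samples (zero before the first sample, last value held afterwards).
On any interval where C_a is linear the ODE has a closed-form solution
and a closed-form time integral, so the simulator propagates the state
across the merged grid of input samples and frame edges and accumulates
exact frame averages — no quadrature error, important because the fitter
inverts this same map and round-trip recovery is tested at 10⁻⁴ relative.
`expm1` is used for the exponential terms so the k₂ → 0 limit is stable;
k₂ = 0 falls back to the polynomial antiderivative.

**Units.** Minutes and kBq/mL throughout; K₁ in mL plasma/min/mL tissue.
The default frame schedule is 12×10 s, 8×30 s, 2×2 min, 4×5 min
(26 frames, 30 min). All curves are assumed decay-corrected to injection
time; an uncorrected path is out of scope.

**Blood input preparation.** The image-derived aorta curve is scaled by
(venous sample activity)/(piecewise-linear image value at the sample
time), typically drawn ~25.7 min post-injection; the scale is kept as
provenance. Metabolite correction multiplies by a user-supplied parent
fraction curve, evaluated at frame mid-times; the default is the identity
because no parent-fraction model is assumed for ¹¹C-acetate — users with
measured parent fractions pass them in.

**ROI fit.** Bounded trust-region nonlinear least squares (scipy
`least_squares`, tolerances 10⁻¹²) minimising Σ wᵢ(C_obs,i − C_model,i)²
with weights ∝ frame duration — an approximation to count-variance
weighting that needs no calibration data. Defaults: init (K₁, k₂, v_b) =
(0.1, 0.1, 0.05), bounds K₁, k₂ ∈ [0, 5], v_b ∈ [0, 1]. An all-zero
observed curve returns K₁ = 0 flagged "unidentifiable k2" (k₂ carries no
information without uptake); a zero input with a zero curve is a
degenerate-input error. v_b can be fixed or fitted — both modes exist
because either convention is common in voxel-wise work.

**Linearized form.** Integrating the model gives the operational linear
form C_PET(t) = θ₁∫C_a + θ₂∫C_PET + θ₃·C_a with θ₃ = v_b, k₂ = −θ₂ and
K₁ = (θ₁ + θ₂θ₃)/(1 − θ₃). Integrals are trapezoid sums on frame
mid-times (from zero). Ordinary least squares on the three regressors is
exact in the dense-frame noise-free limit and agrees with the nonlinear
fit to ≤1% there; on the coarse 26-frame schedule the trapezoid
discretisation biases k₂ by ~1–2%, which is why the ROI path uses the
exact nonlinear fit and the linear form is reserved for voxel-wise
mapping, where its speed and closed form matter. Estimates outside the
bounds are clipped and flagged.

**Voxel-wise spatially constrained ridge.** Two passes over the masked
voxels: (1) unpenalized linearized OLS per voxel; (2) per-voxel ridge
refit minimising ‖y − Xθ‖² + (θ − θ̃)ᵀΛ(θ − θ̃), where θ̃ is the pass-1
estimate smoothed with a 3×3×3 Gaussian kernel (σ = 1 voxel) restricted
to the mask (mask-normalised convolution, so mask edges are not diluted
by background), and Λ = λ·(locally smoothed pass-1 residual variance)·I.
λ defaults to 0.1 and is configuration; λ = 0 reduces to pass 1 exactly.
Voxels with singular pass-1 designs are excluded and counted. Maps hold
NaN outside the valid mask. On a two-region phantom with 10%
multiplicative noise the region-median K₁ and k₂ recover truth within a
few percent (tested at the 10% level).

**Flow and segmentation.** F = K₁/E with E = 0.52 by default. The
average image is the duration-weighted mean over a window (default 40 s
to 4.5 min, partial frames weighted by overlap). Iso-contour ROIs
threshold at a fraction (default 0.5) of the 99th-percentile robust
maximum and keep the largest 26-connected component; the threshold is
deliberately exposed because this step is semi-automatic in practice and
manual masks can always be supplied instead.

## MRI maps

R2\* and ADC estimation are the same log-linear problem: regress ln S on
TE (seconds) or b (s/mm²); the rate is minus the slope. Log-linear OLS is
exact on noise-free exponentials for any ≥2 distinct abscissae and its
bias at 1% multiplicative noise is well under 2% (Monte-Carlo tested). A
weighted variant (weights ∝ signal²) approximates maximum likelihood
under additive noise for low-SNR use. Negative fitted rates are floored
at zero with a diagnostic flag (physical constraint). FSOC =
R2\*_pre − R2\*_post. Kidney volume is voxel count × voxel volume
(mm³ → mL). pCASL perfusion maps are consumed as ready-made values; only
ROI summarisation (arithmetic or geometric mean) applies to them.

## Clearance and Gomez hemodynamics

Per collection period: flow = urine volume/duration; clearance =
U·flow/P̄ with P̄ the mean of the bracketing plasma concentrations.
Periods are averaged; any period deviating >30% from the median is
flagged but never silently dropped. RPF = PAH clearance/e_PAH with
e_PAH = 0.85 by default; a GFR-dependent extraction adjustment is a
pluggable callable because its exact published form varies, and the
choice is recorded in output.

The Gomez equations use Bowman pressure P_Bow = 10 mmHg, gross filtration
coefficient K_FG = 0.1012 mL/s/mmHg (both configurable; a
diabetes-specific K_FG slot is provided since some groups use distinct
values), GFR converted to mL/s inside ΔP_F and R_E, flows in mL/s inside
the resistances, and the factor 1328 converting mmHg·s/mL to
dyne·s·cm⁻⁵. Physically impossible configurations (FF ≥ 1, RBF ≤ GFR,
MAP ≤ P_GLO) raise errors naming the violated constraint rather than
returning negative resistances. RVR = MAP/RBF in conventional
mmHg·min/mL.

## Clamp, DXA and metabolomics

The M-value is the mean glucose infusion rate over the steady-state
window, defaulting to the final 30 minutes of a stage when no window is
given; lean normalisation multiplies by weight/lean mass. NEFA
suppression is 100·(baseline − steady)/baseline and may be negative.
Muscle mass is a·ALM + b with b = −0.63 kg and a = 1.13 by default; both
coefficients are explicit in every report because the published equation
family admits variants. Metabolomics: missing abundances are imputed at
20% of the per-metabolite observed minimum (below-detection-limit
assumption); duplicate tissue sections are averaged per participant;
covariate-adjusted comparisons of the right-skewed abundances go through
the sqrt-scale regression below.

## Statistical layer

Group comparisons: Welch t by default (pooled by flag), Mann-Whitney
exact for groups of ≤8 without ties else tie-corrected normal
approximation, χ² or Fisher for categorical tables. Adjusted means are
OLS least-squares means evaluated at covariate grand means with CIs from
the model error variance; rank-deficient designs raise with the collinear
columns named. Spearman uses average ranks with a t-approximation p; the
covariate-adjusted companion regression is reported separately on the
rank or raw scale (both offered, labelled, since conventions differ).
The two-sample KS statistic is the exact sup-distance of the ECDFs; its
p-value is the asymptotic Kolmogorov series at √(n_a·n_b/(n_a+n_b))·D.
The asymptotic p is conservative for moderate samples — null p-values
calibrate to uniformity only in the large-sample regime (checked at 2000
cells per group), which is the regime the test is meant for. Power for
the two-sided two-sample t test uses the noncentral t with
df = n₁+n₂−2. Raw p-values are reported; Benjamini–Hochberg is available
but off by default, and the choice is recorded in output.

## Synthetic data

Generators are deterministic given (config, seed); noisy generation
refuses to run without an explicit seed. Defaults encode the study
conditions: cohort means M = 7.8 ± 2.6 (T1D) vs 14.3 ± 4.0 (HC)
mg/kg/min, cortical k₂ = 0.16 ± 0.02 vs 0.18 ± 0.02 min⁻¹, medullary
0.15 ± 0.03 vs 0.18 ± 0.02 min⁻¹, log-normal GBM width with medians
521.5 vs 446.7 nm, M–k₂ correlation 0.42; PET phantoms use the 26-frame
schedule with cortex (K₁ = 0.20, k₂ = 0.18, v_b = 0.10) and medulla
(K₁ = 0.10, k₂ = 0.18, v_b = 0.05) blocks and an aorta column carrying
the blood curve. The input function is a gamma-variate A·t^α·e^(−t/β)
(peak 0.5 min, 300 kBq/mL by default, sampled at 1 s for 30 min) — a
standard analytic stand-in for a measured aorta curve. Noise is
multiplicative Gaussian (CV-parameterized) for PET/MRI and additive for
tabular series; CVs were chosen to reproduce the cohort SDs the
generators encode.

What the generators do *not* emulate: anatomical geometry, partial-volume
and spill-over effects, attenuation/scatter artefacts, motion, Rician
MRI noise at low SNR, and physiological drift during clamps. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to every real-world artefact.

## Problem sizes

Defaults in tests and the acceptance script: 8×8×4 phantoms (26 frames),
27-point ROI recovery grids, 100–1000-rep Monte-Carlo loops, 500-rep
coverage studies, 200k-rep power cross-checks — sizes at which every
quantity is stable to well inside its tolerance while the whole suite
runs in well under a minute per stage.

## Known limitations

- The linearized voxel-wise estimator inherits trapezoid bias on coarse
  frame schedules; dense schedules or the nonlinear ROI path avoid it.
- The Gomez framework's constants (K_FG, P_Bow) are population-level
  assumptions; profiles are only as individual as those constants.
- The PAH extraction adjustment for low GFR is configuration, not a
  built-in model.
- Iso-contour segmentation is a convenience; quantitative ROI work should
  review masks manually, as in practice.
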