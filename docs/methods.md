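# Methods

## Signal model and units

Renal DWI signal is modeled as a two-compartment (IVIM) biexponential,

    S(b, g) = S0 · [ fp · exp(−b · gᵀ Dp g) + (1 − fp) · exp(−b · gᵀ Dt g) ],

where `Dt` is the structural diffusion tensor, `Dp` the pseudodiffusion
tensor of microcirculating water (vascular and tubular flow), `fp` the
perfusion signal fraction and `g` the unit gradient direction.
Diffusivities are in μm²/ms throughout; b-values are stored as acquired
(s/mm²) and converted internally to ms/μm² (b = 800 s/mm² ↔ 0.8), so that
b·D is dimensionless at tissue magnitudes.

The emulated protocol uses b = 0, 10, 30, 50, 70, 80, 100, 120, 200, 400,
600, 800 s/mm² with 12 directions per nonzero shell and one b = 0 volume
per series (133 volumes per quadrant). Four quadrants are acquired:
{bipolar, flow-compensated} × {systole, diastole}. The 12-direction set is
a fixed electrostatic-repulsion solution (antipodal Coulomb energy 102.087,
minimum inter-axis angle 38.1°, tensor-design condition number 1.58),
frozen in `renaldwi.directions`.

## Segmented IVIM fitting

Stage 1 regresses ln S on b over the shells with b > 200 s/mm²
(unweighted log-linear least squares), giving `Dt` as the negative slope
and an initial `fp = 1 − S0_extrapolated / S0_measured` (clipped to [0, 1]).
Stage 2 fixes `Dt` and `S0` (the measured b = 0 mean — fixing S0 removes a
three-parameter degeneracy at low fp) and fits `(fp, Dp)` on all b-values
with `fp ∈ [0, 1]`, `Dp ∈ [Dt, 500]`.

Because the model is linear in `fp` at fixed `Dp`, stage 2 is solved as a
profiled one-dimensional problem: the optimal `fp` has a closed form for
each `Dp`, and the profiled SSE is minimized over a 48-point logarithmic
`Dp` grid followed by bounded Brent refinement of the best bracket. This
attains the global constrained minimum more reliably than a small number of
two-dimensional starts (the dense-grid oracle test bounds the SSE within 1%
of a 200×200 grid minimum) at ~0.5 ms per voxel; grid ties resolve to the
smaller `Dp`.

Voxels with fitted `fp < 0.01` are flagged `dp_undefined`: the perfusion
compartment is too small to identify `Dp`. Such voxels are excluded from
ROI means of the pseudodiffusion family only. Nonpositive high-b signals
mark the voxel `failed`; voxel failures never abort a run.

**Identifiability.** Segmented fitting assumes the fast compartment has
fully decayed on the stage-1 shells. The residual contamination of the
b = 400 shell is `fp·exp(−0.4·Dp)` relative to `(1−fp)·exp(−0.4·Dt)`; for
renal magnitudes (Dt ≈ 2, Dp ≳ 20) this is < 0.1% and the noiseless
round-trip recovers all three parameters to better than 0.1% relative. For
Dp below roughly 10·Dt the stage-1 slope is visibly biased and recovery
degrades gracefully; the round-trip validation therefore samples the
identifiable region (Dt ∈ [1.5, 2.5], fp ∈ [0.05, 0.30],
Dp ≥ max(10·Dt, 20)), while noise-robustness checks use the full realistic
parameter range including its hard low-Dp tail.

## Directional (REFMAP) stage

Each direction's b-curve (11 nonzero b plus the shared b = 0) is fit with
the same segmented procedure, giving per-direction `Dt_j, fp_j, Dp_j`. The
`Dt_j` are fit to a symmetric tensor by linear least squares on the design
rows (gx², gy², gz², 2gxgy, 2gxgz, 2gygz); eigendecomposition yields
λ1 ≥ λ2 ≥ λ3 (negatives clamped to 0 and flagged, voxel retained and
counted in QC), MD = (Dtax + 2·Dtrad)/3 (exact by construction),
FA = √(3/2)·√Σ(λi−λ̄)² / √Σλi², Dtax = λ1, Dtrad = (λ2+λ3)/2. Fewer than 6
valid directions, or a rank-deficient design, invalidates the voxel.

The pseudodiffusion "projection" is implemented as a constrained tensor
fit sharing the structural eigenvectors: nonnegative least squares for
amplitudes (a1, a2, a3) in `Dp_j ≈ Σ ai (gj·ei)²`, with Dp,ax = a1,
Dp,rad = (a2+a3)/2, Dp = (a1+a2+a3)/3. This uses all 12 directions and
reduces exactly to an axial/radial eigenframe evaluation when the `Dp_j`
are tensor-consistent — the interpretation we adopt for the one-line
"projected along the axial and radial eigenvectors" recipe. Directions
flagged `dp_undefined` are excluded; fewer than 6 usable directions leaves
the directional pseudodiffusion undefined for that voxel. The scalar
perfusion fraction `f` is the median of `fp_j` over valid directions,
robust to single-direction corruption.

## Synthetic phantom

The phantom is a single-kidney section on the DWI grid: an in-plane
elliptical parenchyma, a cortical strip of configurable thickness,
medullary pyramids as angular wedges whose principal eigenvector points
radially toward the pelvis (inter-wedge gaps remain cortical, as columns of
Bertin), an excluded central pelvis and an optional excluded cyst. Excluded
voxels carry fluid-like parameters (MD 3.0, fp 0) so that ROI-exclusion
logic is consequential.

Per tissue and quadrant, voxel parameters are drawn from normal
distributions parameterized by (MD, FA, fp, Dp) means and SDs. Tensors are
axially symmetric: λ1 = MD(1+2δ), λ2 = λ3 = MD(1−δ) with
δ = FA·√(3/(9−6FA²)), so generated tensors hit the MD and FA targets
exactly. The pseudodiffusion tensor shares the eigenframe with axial
fraction ε: Dp,ax = Dp(1+2ε), Dp,rad = Dp(1−ε); ε defaults to 0.05
(cortex) and 0.30 (medulla), reflecting flow alignment with the radially
oriented tubules. Defaults for the eight (tissue × quadrant) contexts
follow published cardiac-gated renal values — e.g. bipolar/diastole cortex
MD 1.96, FA 0.19, fp 0.16, Dp 25.4; medulla MD 1.89, FA 0.28, fp 0.20,
Dp 50.9 — with flow compensation halving fp (suppressed slow tubular flow)
and systole elevating fp and Dp. Sampled Dp is floored at
max(5, 1.05·λ1/(1−ε)) so pseudodiffusion eigenvalues always exceed the
tissue eigenvalues; the floor intentionally keeps a low-Dp tail that is
hard for segmented fitting, as in vivo.

Noise is Rician: `√((S+σn₁)² + (σn₂)²)` on the magnitude signal, while the
fitters assume Gaussian residuals, as standard. All randomness flows from a
single seed; identical configs are bit-identical.

What the phantom does **not** emulate: organ anatomy beyond the
strip/pyramid geometry, respiratory/cardiac motion, EPI distortion, partial
volume at tissue boundaries, spatially correlated noise, and the
HASTE-resolution segmentation step (masks are native to the DWI grid).
Passing tests therefore validate the estimators and statistics under the
stated generative model, not robustness to acquisition artifacts.

## Virtual cohort

Each subject carries two kidneys with volumes ~N(160, 35²) ml (floored at
40) and a lognormal per-kidney diffusivity "quality" factor with 8% CV
(matching the across-patient CV of medullary axial diffusivity).
Ground-truth ROI metrics per (tissue, waveform, phase) context scale the
population defaults by the quality factor (diffusivity family) and
independent lognormal jitter (FA 6%, fp 12%, Dp 15% CV).

Split true GFR is linked linearly to the designated volume-weighted metric,
by default medullary bipolar/diastole V·Dtax:

    split mGFRt = 5 + 0.10 · (V·Dtax) + u_subject + e_kidney,

with the residual SD calibrated against the empirical SD of V·Dtax so the
population correlation equals the configured target (0.80 by default);
half the residual variance sits at the subject level, inducing the
within-subject correlation the bilateral statistics must handle. Setting
`residual_sd = 0` gives an exact link (r = 1). Totals are sums over sides,
so SRF = split/total sums to 1 exactly; mGFR = mGFRt·1.73/BSA with
BSA ~ N(1.9, 0.2²) m²; eGFR adds noise calibrated to a target eGFR-mGFR
correlation (0.735 by default). Proteinuria (prevalence 0.15) multiplies
diffusivities by 0.932, FA by 0.823, fp by 0.614 and Dp by 0.532 —
the published group contrasts.

Cohort tables are generated for any n; full 4-quadrant DWI bundles
(NIfTI + bval/bvec + masks + TSV) are written for a caller-chosen subset of
subjects, since the table-level statistics do not require image synthesis.

## Statistics

**Bilateral correlation.** Two kidneys per subject are repeated
measurements. We fit a bivariate linear mixed model with subject-level
random intercepts for both variables by maximum likelihood (between-subject
covariance Σb, within-subject Σw, each 2×2; per-subject covariance
kron(Σb, J) + kron(Σw, I)). The reported r is the total correlation
`(Σb+Σw)₀₁ / √((Σb+Σw)₀₀(Σb+Σw)₁₁)`. SE(r) comes from the observed
information via the delta method; the 95% CI transforms r to Fisher-z with
the delta-method SE (`ci_method="fisher-n"` substitutes 1/√(n_subjects−3));
the two-sided P is the Wald test on the z scale. Monte-Carlo calibration
(500 replicates, 200 subjects × 2 kidneys, true total r = 0.7) shows
estimate bias < 0.01 and CI coverage within 95% ± 3%. With one kidney per
subject the model degenerates to independent sampling and the routine
returns the exact Pearson result (flagged); an exactly collinear input or a
singular within-subject structure falls back to subject-mean Pearson,
flagged.

**Multiple comparisons.** Benjamini-Hochberg step-up adjustment
(`adjᵢ = min_{j≥i} (m/j)·p₍ⱼ₎`, capped at 1), applied per table family —
one 36-test family per gradient waveform (metric × tissue × phase), the
grouping that reproduces the published adjusted columns. Printed "<0.001"
entries are encoded as 0.0005 when re-deriving published worked examples
(any encoding ≤ 0.002 gives identical adjusted values for the numeric
entries). Note the step-up map is not idempotent in general (e.g.
[0.2, 0.5] → [0.4, 0.5] → [0.5, 0.5]); its contract is monotonicity along
the sorted inputs, adj ≥ raw, adj ≤ 1.

**Mixed-effects LASSO.** y = Xβ + Z u + ε with subject random intercepts
u. Predictors are standardized internally. For each penalty α the solver
iterates (three rounds): GLS whitening under the current compound-symmetry
covariance (closed form per subject block), an L1 fixed-effects fit on the
whitened data (coordinate descent via scikit-learn's Lasso, intercept
partialled out unpenalized), and ML re-estimation of (τ², σ²) from the
current residuals. The penalty path (25 values, geometric, from the
all-zero threshold down 3 decades) is scored by subject-grouped K-fold
(K = 5, folds assigned by seeded permutation of subjects) held-out Gaussian
deviance under the training-fold marginal covariance; the minimizing α is
refit on all data. Reported R² is marginal — the squared correlation of
fixed-effect predictions with the outcome (conditional R², adding BLUP
subject intercepts, is also emitted). The original-scale intercept is
defined as mean(y − Xβ), so the fully shrunk model reports the grand mean
exactly and R² = 0. Constant predictors are dropped with a warning.

**Other tests.** eGFR-augmentation uses OLS of mGFR on eGFR plus one
metric (optionally plus volume); the metric's added value is the two-sided
t-test of its coefficient (perfect base fits with numerically zero metric
coefficients report P = 1). Collinear predictor pairs are rejected by name.
Proteinuria contrasts use Welch's unequal-variance two-sample t-test, which
reproduces the published P from the printed group summaries far better than
the pooled test under the 22-vs-4 group sizes. Complete-case handling
applies throughout (the clinical subsets differ in n).

## Problem sizes and numerical choices

Validation workloads are sized for interactive runs: noiseless round-trips
use 500-1000 voxels; the SNR-50 robustness check uses ~1100 medulla voxels
of a 48×48×3 phantom; directional round trips use a 16×16×1 section
(~80 voxels × 12 directions); cohort statistics use 200 subjects; CI
calibration uses 500 replicates; LASSO support recovery uses 50 replicates
of 60 subjects × 24 candidates. Stage-2 tolerance is 1e-10 on the Dp
bracket; eigenvalue clamping is at exactly 0; the fp floor is 0.01;
Dp bounds are [Dt, 500] μm²/ms, covering published renal values (~20-60)
with ample headroom.

## Known limitations

- The segmented estimator is intrinsically biased where Dp approaches Dt
  (slow microcirculation); this is a property of the method, faithfully
  reproduced, not a defect of the implementation.
- Stage-1 log-linear regression is unweighted; a variance-weighted
  alternative is documented but not implemented.
- The bilateral-correlation model assumes a shared compound-symmetry
  structure across subjects and Gaussian marginals.
- The virtual cohort's link model is a minimal linear construction for
  validating the statistics; it does not claim physiological realism
  beyond the configured magnitudes, contrasts and correlation targets.
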