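# renaldwi

Cardiac-gated renal diffusion-MRI analysis: IVIM + DTI ("REFMAP") parameter
estimation, per-kidney aggregation with volume weighting, and the cohort
statistics that relate imaging metrics to measured and estimated glomerular
filtration rate (GFR) and proteinuria.

## Who this is for

Renal MRI researchers who want a tested, reusable implementation of the
4-quadrant cardiac-gated DWI analysis chain — and a synthetic phantom /
virtual-cohort generator that makes every stage verifiable without patient
data. Both kidneys of each subject are handled as repeated measurements
throughout.

## The model

The diffusion-weighted signal of renal tissue is biexponential
(intravoxel incoherent motion, IVIM):

    S(b) / S0 = fp · exp(−b · Dp) + (1 − fp) · exp(−b · Dt)

with tissue diffusivity `Dt` (μm²/ms), perfusion signal fraction `fp`, and
pseudodiffusivity `Dp` of microcirculating water. Fitting is *segmented*:
`Dt` from a log-linear fit to the high-b shells (b > 200 s/mm²), then
`(fp, Dp)` from all b-values with `Dt` frozen.

The directional stage repeats the segmented fit per gradient direction,
fits the per-direction `Dt_j` to a diffusion tensor (eigenvalues
λ1 ≥ λ2 ≥ λ3; MD, FA, axial Dtax = λ1, radial Dtrad = (λ2+λ3)/2) and
projects the per-direction pseudodiffusivities `Dp_j` onto the structural
eigenframe by nonnegative least squares, giving Dp,ax, Dp,rad and
Dp = (Dp,ax + 2·Dp,rad)/3.

Acquisition quadrants combine gradient waveform (bipolar / flow-compensated)
with cardiac phase (systole / diastole); flow compensation nulls coherent
slow-flow decay while systolic triggering maximizes vascular inflow, so the
four quadrants emphasize tubular vs vascular contributions differently.

Per kidney, ROI means over cortex and medulla (lesions/cysts/pelvis
excluded) are optionally volume-weighted (V∗metric), and single-kidney GFR
is `split mGFR = mGFR × SRF`. The statistics layer provides bilateral
repeated-measures correlations (bivariate random-intercept mixed model),
Benjamini-Hochberg adjustment, mixed-effects LASSO with subject-grouped
cross-validation, eGFR-augmentation regressions, and Welch group tests.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/03_cohort_statistics.py` generates a 200-subject virtual
cohort whose volume-weighted medullary axial diffusivity is linked to split
kidney function with a configured correlation of 0.80, then recovers it:

```
V*Dtax (medulla/bipolar/diastole) vs split mGFRt:
  r = 0.809  SE 0.018  95% CI (0.771, 0.841)  P = 1.13e-106   [configured target 0.80]
eGFR vs mGFR: r = 0.773 (P = 4.9e-41)   [configured target 0.735]
...
LASSO (volume-weighted IVIM vs split mGFRt): marginal R^2 = 0.653, 7/24 predictors retained
proteinuria, cortical fp (bipolar/systole): 0.212 vs 0.131 (Welch t = 32.31, ...)
```

The mixed-model `r` is the total (between + within subject) correlation
over 400 kidneys of 200 subjects; the LASSO R² is the squared correlation
of the fixed-effect predictions with the outcome; the proteinuria contrast
reflects the configured 38.6% perfusion-fraction reduction in positive
kidneys.

A thin CLI wraps the same stages for file-based use:
`renaldwi simulate | fit-ivim | fit-refmap | summarize | stats`.

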