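"""Virtual-cohort statistics: bilateral mixed-model correlations with BH
adjustment, the mixed-effects LASSO, and proteinuria group tests.

A 200-subject cohort is generated with a configured correlation of 0.80
between volume-weighted medullary axial diffusivity (V*Dtax) and split true
GFR, and 0.735 between eGFR and mGFR; the statistics layer recovers both.
"""

import numpy as np

from renaldwi import CohortConfig, make_cohort
from renaldwi.roi import volume_weight_table
from renaldwi.stats import correlation_table, lasso_mixed, mixed_corr, pearson, proteinuria_test

cohort = make_cohort(CohortConfig(n_subjects=200, seed=7))
k = cohort.kidneys

# headline bilateral correlation (repeated-measures: 2 kidneys per subject)
metric, tissue, wave, ph = cohort.config.link_metric
sel = k[(k.tissue == tissue) & (k.waveform == wave) & (k.phase == ph)].copy()
sel = volume_weight_table(sel, [metric])
res = mixed_corr(sel[f"V*{metric}"], sel["split_mGFRt"], sel["subject_id"])
print(f"V*{metric} ({tissue}/{wave}/{ph}) vs split mGFRt:")
print(f"  r = {res.r:.3f}  SE {res.se:.3f}  95% CI ({res.ci_low:.3f}, {res.ci_high:.3f})"
      f"  P = {res.p:.2e}   [configured target 0.80]")

subj = cohort.subjects.drop_duplicates("subject_id")
r, p = pearson(subj["eGFR"], subj["mGFR"])
print(f"eGFR vs mGFR: r = {r:.3f} (P = {p:.1e})   [configured target 0.735]")

# full per-context volume-weighted table with BH adjustment (one family per
# waveform, mirroring the published table layout)
kw = volume_weight_table(k.copy(), ["MD", "Dtax", "fp"])
table = correlation_table(kw, ["V*MD", "V*Dtax", "V*fp"], "split_mGFRt")
print("\ntop volume-weighted contexts by |r| (BH-adjusted per waveform family):")
top = table.reindex(table["r"].abs().sort_values(ascending=False).index).head(5)
print(top[["Metric", "Tissue", "Sequence", "Phase", "r", "P", "adjusted_P"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# mixed-effects LASSO on the volume-weighted IVIM contexts
wide = k.pivot_table(index=["subject_id", "side"],
                     columns=["tissue", "waveform", "phase"],
                     values=["Dt", "fp", "Dp"])
wide.columns = ["_".join(c) for c in wide.columns]
per_kidney = k.drop_duplicates(["subject_id", "side"]).set_index(["subject_id", "side"])
vw = wide.mul(per_kidney.loc[wide.index, "volume_ml"], axis=0)
model = lasso_mixed(vw, per_kidney.loc[wide.index, "split_mGFRt"].to_numpy(),
                    wide.index.get_level_values("subject_id").to_numpy(), seed=7)
print(f"\nLASSO (volume-weighted IVIM vs split mGFRt): marginal R^2 = "
      f"{model.r2_marginal:.3f}, {np.sum(model.coef != 0)}/{len(model.coef)} "
      f"predictors retained at alpha = {model.alpha:.3g}")

# proteinuria contrast in the cortex/bipolar/systole context
ctx = k[(k.tissue == "cortex") & (k.waveform == "bipolar") & (k.phase == "systole")]
t = proteinuria_test(ctx["fp"], ctx["proteinuria"])
print(f"\nproteinuria, cortical fp (bipolar/systole): {t.mean_neg:.3f} vs "
      f"{t.mean_pos:.3f} (Welch t = {t.t:.2f}, df = {t.df:.1f}, P = {t.p:.1e})")
print("positive kidneys carry the configured ~38.6% lower perfusion fraction.")
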