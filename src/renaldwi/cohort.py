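"""Virtual patient cohort with the correlation structure the analysis assumes.

Each subject carries two kidneys.  A per-kidney multiplicative "tissue
quality" factor perturbs the diffusivity family around the population
defaults; per-kidney ROI-level ground-truth metrics are drawn for every
(waveform, phase, tissue) context.  Split (single-kidney) true GFR is linked
linearly to the designated volume-weighted metric V*Dtax with a subject-level
plus kidney-level residual whose SD is calibrated so that the population
correlation matches a configured target.  Totals follow by summation; the
split renal function SRF is emergent (split / total) and therefore sums to 1
exactly.  BSA-normalized mGFR = mGFRt * 1.73 / BSA, and eGFR is mGFR plus
calibrated noise targeting a configured eGFR-mGFR correlation.

Proteinuria-positive subjects receive multiplicative parameter shifts
(lower diffusivities, perfusion fractions, pseudodiffusivities and FA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import QUADRANTS, write_mask, write_series, write_subject_table
from .synthetic import (
    ConfigurationError,
    PhantomConfig,
    _eigs_from_md_fa,
    make_phantom,
    scaled_tissue_params,
    synthesize_dwi,
)

#: metrics recorded per kidney and context
KIDNEY_METRICS = ("Dt", "fp", "Dp", "MD", "FA", "Dtax", "Dtrad", "Dpax", "Dprad")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 27
    seed: int = 0
    volume_mean: float = 160.0  # ml, per kidney
    volume_sd: float = 35.0
    quality_cv: float = 0.08  # lognormal CV of the per-kidney diffusivity factor
    fa_cv: float = 0.06
    fp_cv: float = 0.12
    dp_cv: float = 0.15
    # split mGFRt link: split = intercept + slope * (V * Dtax) + residual
    link_metric: tuple[str, str, str, str] = ("Dtax", "medulla", "bipolar", "diastole")
    link_intercept: float = 5.0
    link_slope: float = 0.10  # ml/min per (ml * um^2/ms)
    target_r: float | None = 0.80  # V*Dtax vs split mGFRt
    residual_sd: float | None = None  # overrides target_r when set
    between_subject_frac: float = 0.5  # residual variance at subject level
    bsa_mean: float = 1.90  # m^2
    bsa_sd: float = 0.20
    target_r_egfr: float | None = 0.735  # eGFR vs mGFR
    egfr_noise_sd: float | None = None
    proteinuria_prevalence: float = 0.15
    # multiplicative shifts applied to proteinuria-positive kidneys
    shift_diffusivity: float = -0.068
    shift_fp: float = -0.386
    shift_dp: float = -0.468
    shift_fa: float = -0.177

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.volume_mean <= 0:
            raise ConfigurationError("volumes must be positive")
        if self.residual_sd is None:
            if self.target_r is None or not 0.0 < self.target_r < 1.0:
                raise ConfigurationError(
                    "target correlation must lie in (0, 1); use residual_sd=0 "
                    "for an exact (r=1) link"
                )
        elif self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")
        if self.egfr_noise_sd is None and self.target_r_egfr is not None:
            if not 0.0 < self.target_r_egfr <= 1.0:
                raise ConfigurationError("target eGFR-mGFR correlation must be in (0, 1]")
        if not 0.0 <= self.proteinuria_prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")


@dataclass
class Cohort:
    subjects: pd.DataFrame  # one row per (subject, side); totals + SRF
    kidneys: pd.DataFrame  # long: context x kidney ground-truth metrics
    residual_sd: float
    egfr_sd: float
    config: CohortConfig


def make_cohort(config: CohortConfig, phantom: PhantomConfig | None = None) -> Cohort:
    """Draw the virtual cohort tables (deterministic under ``config.seed``).

    ``phantom`` supplies the population parameter defaults (its
    ``tissue_params``); geometry is irrelevant at table level and is only
    used when DWI bundles are written via :func:`write_cohort`.
    """
    config.validate()
    if phantom is None:
        phantom = PhantomConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sides = ("L", "R")

    prot = (rng.random(n) < config.proteinuria_prevalence).astype(int)
    bsa = np.clip(rng.normal(config.bsa_mean, config.bsa_sd, n), 1.2, 2.8)
    volumes = np.clip(
        rng.normal(config.volume_mean, config.volume_sd, (n, 2)), 40.0, None
    )
    quality = np.exp(rng.normal(0.0, config.quality_cv, (n, 2)))

    sd = 1.0 + config.shift_diffusivity
    sfa = 1.0 + config.shift_fa
    sfp = 1.0 + config.shift_fp
    sdp = 1.0 + config.shift_dp

    rows = []
    for i in range(n):
        for k, side in enumerate(sides):
            q = quality[i, k]
            for (wave, ph) in QUADRANTS:
                for tissue in ("cortex", "medulla"):
                    tp = phantom.tissue_params[(wave, ph)][tissue]
                    md = tp.md * q
                    fa = tp.fa * np.exp(rng.normal(0.0, config.fa_cv))
                    fp = tp.fp * np.exp(rng.normal(0.0, config.fp_cv))
                    dp = tp.dp * np.exp(rng.normal(0.0, config.dp_cv))
                    if prot[i]:
                        md, fa, fp, dp = md * sd, fa * sfa, fp * sfp, dp * sdp
                    fa = min(fa, 0.92)
                    l1, lrad = _eigs_from_md_fa(md, fa)
                    dpax = dp * (1 + 2 * tp.pseudo_aniso)
                    dprad = dp * (1 - tp.pseudo_aniso)
                    rows.append(
                        {
                            "subject_id": f"S{i:03d}",
                            "side": side,
                            "tissue": tissue,
                            "waveform": wave,
                            "phase": ph,
                            "volume_ml": volumes[i, k],
                            "proteinuria": int(prot[i]),
                            "Dt": md,
                            "fp": fp,
                            "Dp": dp,
                            "MD": md,
                            "FA": fa,
                            "Dtax": l1,
                            "Dtrad": lrad,
                            "Dpax": dpax,
                            "Dprad": dprad,
                        }
                    )
    kidneys = pd.DataFrame(rows)

    metric, tissue, wave, ph = config.link_metric
    link = kidneys[
        (kidneys.tissue == tissue) & (kidneys.waveform == wave) & (kidneys.phase == ph)
    ].set_index(["subject_id", "side"])
    x = (link["volume_ml"] * link[metric]).to_numpy()  # kidney order: subj x side

    if config.residual_sd is not None:
        sigma = float(config.residual_sd)
    else:
        sx = float(np.std(x))
        sigma = abs(config.link_slope) * sx * np.sqrt(1.0 / config.target_r**2 - 1.0)
    frac = config.between_subject_frac
    u = rng.normal(0.0, sigma * np.sqrt(frac), n)  # subject level
    e = rng.normal(0.0, sigma * np.sqrt(1.0 - frac), (n, 2))  # kidney level
    split_t = config.link_intercept + config.link_slope * x.reshape(n, 2)
    split_t = np.clip(split_t + u[:, None] + e, 0.5, None)

    mgfrt_total = split_t.sum(axis=1)
    srf = split_t / mgfrt_total[:, None]
    mgfr_total = mgfrt_total * 1.73 / bsa
    if config.egfr_noise_sd is not None:
        eg_sd = float(config.egfr_noise_sd)
    elif config.target_r_egfr is None or config.target_r_egfr == 1.0:
        eg_sd = 0.0
    else:
        eg_sd = float(np.std(mgfr_total)) * np.sqrt(1.0 / config.target_r_egfr**2 - 1.0)
    egfr = np.clip(mgfr_total + rng.normal(0.0, eg_sd, n), 2.0, None)

    subj_rows = []
    for i in range(n):
        for k, side in enumerate(sides):
            subj_rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "side": side,
                    "volume_ml": volumes[i, k],
                    "eGFR": egfr[i],
                    "mGFR": mgfr_total[i],
                    "mGFRt": mgfrt_total[i],
                    "SRF": srf[i, k],
                    "proteinuria": int(prot[i]),
                    "BSA": bsa[i],
                    "split_mGFR": mgfr_total[i] * srf[i, k],
                    "split_mGFRt": split_t[i, k],
                }
            )
    subjects = pd.DataFrame(subj_rows)

    kidneys = kidneys.merge(
        subjects[["subject_id", "side", "split_mGFR", "split_mGFRt", "eGFR", "mGFR", "mGFRt"]],
        on=["subject_id", "side"],
    )
    return Cohort(subjects, kidneys, sigma, eg_sd, config)


def kidney_phantom_config(
    phantom: PhantomConfig, cohort: Cohort, subject_id: str, side: str, seed: int
) -> PhantomConfig:
    """Per-kidney phantom config: population geometry with this kidney's
    ground-truth parameter scales."""
    ref = cohort.kidneys
    row = ref[
        (ref.subject_id == subject_id)
        & (ref.side == side)
        & (ref.tissue == "cortex")
        & (ref.waveform == "bipolar")
        & (ref.phase == "diastole")
    ].iloc[0]
    base = phantom.tissue_params[("bipolar", "diastole")]["cortex"]
    return replace(
        phantom,
        tissue_params=scaled_tissue_params(
            phantom.tissue_params,
            md_scale=row["MD"] / base.md,
            fa_scale=row["FA"] / base.fa,
            fp_scale=row["fp"] / base.fp,
            dp_scale=row["Dp"] / base.dp,
        ),
        seed=seed,
    )


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    phantom: PhantomConfig | None = None,
    write_dwi_subjects: int = 0,
    noise_sigma: float | None = None,
) -> Path:
    """Write ``subjects.tsv`` and ``kidney_truth.tsv``; optionally synthesize
    and write 4-quadrant DWI bundles (NIfTI + bval/bvec + masks) for the
    first ``write_dwi_subjects`` subjects (both kidneys)."""
    from .io import AcquisitionScheme

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subject_table(cohort.subjects, out / "subjects.tsv")
    cohort.kidneys.to_csv(out / "kidney_truth.tsv", sep="\t", index=False)
    if write_dwi_subjects > 0:
        if phantom is None:
            phantom = PhantomConfig()
        sigma = phantom.noise_sigma if noise_sigma is None else noise_sigma
        ids = cohort.subjects["subject_id"].unique()[:write_dwi_subjects]
        for si, sid in enumerate(ids):
            for ki, side in enumerate(("L", "R")):
                seed = cohort.config.seed * 100003 + si * 101 + ki
                pcfg = kidney_phantom_config(phantom, cohort, sid, side, seed)
                truth = make_phantom(pcfg)
                kdir = out / sid / side
                kdir.mkdir(parents=True, exist_ok=True)
                masks = truth.mask_set()
                for name in ("parenchyma", "cortex", "medulla", "excluded"):
                    write_mask(getattr(masks, name), kdir / f"{name}.nii.gz",
                               voxel_size=truth.voxel_size)
                for qi, (wave, ph) in enumerate(QUADRANTS):
                    scheme = AcquisitionScheme.study_scheme(wave, ph)
                    series = synthesize_dwi(truth, scheme, sigma, seed=seed * 7 + qi)
                    write_series(series, kdir / f"dwi_{wave}_{ph}")
    return out
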