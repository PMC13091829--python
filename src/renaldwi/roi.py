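"""ROI aggregation, volume weighting and split-function arithmetic.

Voxel maps are reduced to per-kidney, per-tissue, per-quadrant means over
valid voxels only: the pseudodiffusion family (Dp, Dpax, Dprad) additionally
excludes voxels whose perfusion fraction fell below the floor (status
``dp_undefined``), while the tissue-diffusivity family excludes only failed
voxels.  Excluded labels (lesion / cyst / pelvis / vessel) never contribute.

Volume weighting multiplies each ROI mean by the kidney's parenchymal volume
(V*metric), and split kidney function is obtained by multiplying total
mGFR/mGFRt by the kidney's split renal function fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MaskSet
from .ivim import STATUS_FAILED, STATUS_OK

logger = logging.getLogger(__name__)

#: metrics whose means require fully valid (status ok) voxels
DP_FAMILY = frozenset({"Dp", "Dpax", "Dprad"})


def summarize_roi(
    maps: dict[str, np.ndarray], mask_set: MaskSet, tissue: str
) -> dict[str, tuple[float, int]]:
    """Per-metric ROI means and valid-voxel counts for one tissue.

    ``maps`` must contain a ``"status"`` volume alongside the metric maps.
    Returns ``{metric: (mean, n_valid)}``; metrics with zero valid voxels are
    omitted (and logged).
    """
    roi = mask_set.tissue(tissue)
    if not roi.any():
        raise ValueError(f"empty ROI for tissue {tissue!r} after exclusions")
    status = maps["status"]
    out: dict[str, tuple[float, int]] = {}
    for metric, vol in maps.items():
        if metric == "status":
            continue
        if metric in DP_FAMILY:
            valid = roi & (status == STATUS_OK)
        else:
            valid = roi & (status != STATUS_FAILED)
        valid = valid & np.isfinite(vol)
        n = int(valid.sum())
        if n == 0:
            logger.warning("no valid voxels for metric %s in %s", metric, tissue)
            continue
        out[metric] = (float(vol[valid].mean()), n)
    return out


def kidney_record(
    subject_id: str,
    side: str,
    tissue: str,
    waveform: str,
    phase: str,
    summaries: dict[str, tuple[float, int]],
    volume_ml: float,
    **extra,
) -> dict:
    """Flatten one ROI summary into a long-format record row."""
    row = {
        "subject_id": subject_id,
        "side": side,
        "tissue": tissue,
        "waveform": waveform,
        "phase": phase,
        "volume_ml": volume_ml,
    }
    for metric, (mean, n) in summaries.items():
        row[metric] = mean
        row[f"n_{metric}"] = n
    row.update(extra)
    return row


def volume_weight(record: dict | pd.Series, metrics) -> dict:
    """Add ``V*<metric>`` fields: parenchymal volume times the ROI mean."""
    vol = record.get("volume_ml", None)
    if vol is None or not np.isfinite(vol) or vol <= 0:
        raise ValueError("volume_ml must be present and positive")
    out = dict(record)
    for m in metrics:
        if m in out and out[m] is not None:
            out[f"V*{m}"] = vol * out[m]
    return out


def volume_weight_table(df: pd.DataFrame, metrics, volume_col: str = "volume_ml") -> pd.DataFrame:
    """Vectorized volume weighting over a long-format kidney table."""
    if volume_col not in df.columns:
        raise ValueError(f"missing {volume_col} column")
    if (df[volume_col] <= 0).any() or df[volume_col].isna().any():
        raise ValueError("volumes must be present and positive")
    out = df.copy()
    for m in metrics:
        if m in df.columns:
            out[f"V*{m}"] = df[volume_col] * df[m]
    return out


def split_function(mgfr_total: float, mgfrt_total: float, srf_side: float):
    """Single-kidney GFR: totals times the kidney's SRF fraction."""
    if not 0.0 <= srf_side <= 1.0:
        raise ValueError(f"SRF must lie in [0, 1], got {srf_side}")
    return mgfr_total * srf_side, mgfrt_total * srf_side


def records_table(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)
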