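"""Segmented biexponential IVIM fitting.

Signal model (b in ms/um^2, diffusivities in um^2/ms):

    S(b) = S0 * [ fp * exp(-b * Dp) + (1 - fp) * exp(-b * Dt) ]

where Dt is the tissue diffusivity, fp the perfusion (flowing-spin) signal
fraction and Dp the pseudodiffusivity of the microcirculating compartment.

The segmented procedure fits in two stages:

1. log-linear least squares on the high-b shells (b > 200 s/mm2), where the
   fast compartment has decayed away, giving Dt and an initial fp from the
   extrapolated intercept;
2. a fit on all b-values with Dt frozen and S0 fixed to the measured b=0
   mean, estimating (fp, Dp).

Stage 2 exploits that for fixed Dp the model is linear in fp, so the
two-parameter problem reduces to a 1-D profiled search over Dp (coarse
logarithmic grid plus bounded Brent refinement).  This finds the global
constrained minimum far more reliably than a handful of 2-D starts; ties
resolve to the smaller Dp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import DwiSeries

# voxel fit status codes
STATUS_OK = 0
STATUS_DP_UNDEFINED = 1  # fp below floor; Dp not interpretable
STATUS_FAILED = 2

#: fp below this floor leaves Dp undetermined.
FP_FLOOR = 0.01
#: Upper bound on Dp, um^2/ms; generous headroom over renal values (~25-60).
DP_MAX = 500.0
#: Stage-1 high-b threshold, ms/um^2 (200 s/mm2).
HIGHB_THRESHOLD = 0.2


class SchemeError(ValueError):
    """The acquisition scheme cannot support the requested fit."""


@dataclass
class IvimFit:
    """Per-voxel segmented-fit result."""

    S0: float
    Dt: float
    fp: float
    Dp: float
    status: int = STATUS_OK
    stage1_residual: float = np.nan
    stage2_residual: float = np.nan

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def signal_model(b, S0, fp, Dt, Dp):
    """Biexponential IVIM signal; ``b`` in ms/um^2 (scalar or array)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    return S0 * (fp * np.exp(-b * Dp) + (1.0 - fp) * np.exp(-b * Dt))


def fit_stage1_highb(signals, b, threshold: float = HIGHB_THRESHOLD):
    """Monoexponential log-linear fit on b > threshold.

    Returns ``(Dt, fp_init, S0_extrapolated)``; ``Dt`` is the negative slope
    of ln(S) vs b and ``fp_init = 1 - S0_extrapolated / S0_measured`` clipped
    to [0, 1].  Raises :class:`SchemeError` if fewer than two distinct high-b
    shells exist; returns ``None`` (caller marks the voxel failed) if a
    high-b signal is nonpositive.
    """
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b, dtype=float)
    hi = b > threshold
    if np.unique(b[hi]).size < 2:
        raise SchemeError(
            f"need >=2 distinct b-values above {threshold} ms/um^2, "
            f"got {np.unique(b[hi]).size}"
        )
    if not np.any(b == 0):
        raise SchemeError("a b=0 measurement is required")
    s_hi = signals[hi]
    if np.any(s_hi <= 0):
        return None
    slope, intercept = np.polyfit(b[hi], np.log(s_hi), 1)
    dt = -slope
    s0_meas = float(np.mean(signals[b == 0]))
    s0_extrap = float(np.exp(intercept))
    fp_init = float(np.clip(1.0 - s0_extrap / s0_meas, 0.0, 1.0))
    resid = float(np.sum((np.log(s_hi) - (slope * b[hi] + intercept)) ** 2))
    return dt, fp_init, s0_extrap, resid


def _profiled_sse(dp, s_norm, b, exp_dt):
    """SSE over fp in [0,1] at fixed Dp (fp solved in closed form)."""
    w = np.exp(-b * dp) - exp_dt
    r = s_norm - exp_dt
    denom = float(w @ w)
    fp = float(np.clip((w @ r) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    resid = r - fp * w
    return float(resid @ resid), fp


_DP_GRID_N = 48


def fit_stage2_constrained(signals, b, Dt_fixed, fp_init=None, S0=None):
    """All-b fit of (fp, Dp) with Dt frozen and S0 fixed to the b=0 mean.

    Returns ``(fp, Dp, status, sse)``.  ``fp_init`` is accepted for interface
    compatibility; the profiled search does not need a starting point.
    """
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b, dtype=float)
    if Dt_fixed <= 0:
        return 0.0, np.nan, STATUS_FAILED, np.nan
    if S0 is None:
        S0 = float(np.mean(signals[b == 0]))
    if S0 <= 0:
        return 0.0, np.nan, STATUS_FAILED, np.nan
    s_norm = signals / S0
    exp_dt = np.exp(-b * Dt_fixed)
    lo, hi = Dt_fixed, DP_MAX
    grid = np.geomspace(lo, hi, _DP_GRID_N)
    sses = np.empty(grid.size)
    for i, dp in enumerate(grid):
        sses[i], _ = _profiled_sse(dp, s_norm, b, exp_dt)
    k = int(np.argmin(sses))  # ties -> first (smaller Dp)
    bl = grid[max(k - 1, 0)]
    bu = grid[min(k + 1, grid.size - 1)]
    if bu > bl:
        res = minimize_scalar(
            lambda d: _profiled_sse(d, s_norm, b, exp_dt)[0],
            bounds=(bl, bu),
            method="bounded",
            options={"xatol": 1e-10},
        )
        dp_best = float(res.x) if res.fun <= sses[k] else float(grid[k])
    else:
        dp_best = float(grid[k])
    sse, fp = _profiled_sse(dp_best, s_norm, b, exp_dt)
    status = STATUS_DP_UNDEFINED if fp < FP_FLOOR else STATUS_OK
    return fp, dp_best, status, sse * S0**2


def fit_voxel(signals, b) -> IvimFit:
    """Full segmented fit of one voxel's b-curve (``b`` in ms/um^2)."""
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b, dtype=float)
    s0_meas = float(np.mean(signals[b == 0]))
    stage1 = fit_stage1_highb(signals, b)
    if stage1 is None or s0_meas <= 0:
        return IvimFit(s0_meas, np.nan, np.nan, np.nan, STATUS_FAILED)
    dt, fp_init, _s0x, res1 = stage1
    if dt <= 0:
        return IvimFit(s0_meas, dt, np.nan, np.nan, STATUS_FAILED, res1)
    fp, dp, status, sse = fit_stage2_constrained(signals, b, dt, fp_init, s0_meas)
    return IvimFit(s0_meas, dt, fp, dp, status, res1, sse)


def direction_average(series: DwiSeries):
    """Arithmetic mean of signals over directions at each unique b.

    Returns ``(avg, b_unique)`` with ``avg`` of shape (x, y, z, n_b) and
    ``b_unique`` in ms/um^2 (ascending, includes 0).
    """
    b = series.scheme.b_ms_um2
    b_unique = np.unique(b)
    avg = np.empty(series.shape + (b_unique.size,), dtype=float)
    for i, bu in enumerate(b_unique):
        avg[..., i] = series.data[..., b == bu].mean(axis=-1)
    return avg, b_unique


def fit_voxelwise_average(series: DwiSeries, mask: np.ndarray) -> dict[str, np.ndarray]:
    """Scalar IVIM maps from direction-averaged signals.

    Returns a dict of maps ``{"S0", "Dt", "fp", "Dp", "status"}`` over the
    series grid; voxels outside the mask carry NaN (status FAILED).  Voxel
    failures are recorded in the status map, never raised.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("empty mask")
    avg, b_unique = direction_average(series)
    shape = series.shape
    maps = {k: np.full(shape, np.nan) for k in ("S0", "Dt", "fp", "Dp")}
    status = np.full(shape, STATUS_FAILED, dtype=np.int8)
    for idx in zip(*np.nonzero(mask)):
        fit = fit_voxel(avg[idx], b_unique)
        maps["S0"][idx] = fit.S0
        maps["Dt"][idx] = fit.Dt
        maps["fp"][idx] = fit.fp
        maps["Dp"][idx] = fit.Dp
        status[idx] = fit.status
    maps["status"] = status
    return maps
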