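"""Directional IVIM + DTI stage (the REFMAP parameter set).

Per voxel:

1. the b-dependence of each gradient direction is fit with the segmented
   biexponential (:mod:`renaldwi.ivim`), giving per-direction Dt_j, fp_j, Dp_j;
2. the per-direction tissue diffusivities Dt_j are fit to a standard rank-2
   diffusion tensor by linear least squares, yielding eigenvalues
   l1 >= l2 >= l3, eigenvectors e1..e3, MD, FA, axial (Dtax = l1) and radial
   (Dtrad = (l2+l3)/2) diffusivity;
3. the per-direction pseudodiffusivities Dp_j are projected onto the
   structural eigenframe: nonnegative least squares for amplitudes (a1,a2,a3)
   in Dp_j ~= sum_i a_i (g_j . e_i)^2, a constrained tensor fit sharing
   e1..e3 with the structural tensor.  Dp_ax = a1, Dp_rad = (a2+a3)/2,
   Dp = (a1+a2+a3)/3 (exact by construction).

The scalar perfusion fraction f is the median of fp_j over valid directions,
robust to single-direction failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .directions import tensor_design_matrix, tensor_from_components
from .io import DwiSeries
from .ivim import STATUS_DP_UNDEFINED, STATUS_FAILED, STATUS_OK, fit_voxel

MIN_DIRECTIONS = 6

REFMAP_METRICS = ("MD", "FA", "Dtax", "Dtrad", "f", "Dp", "Dpax", "Dprad")


@dataclass
class TensorFit:
    tensor: np.ndarray  # symmetric 3x3
    evals: np.ndarray  # descending, >= 0 after clamping
    evecs: np.ndarray  # columns e1, e2, e3
    clamped: bool = False
    valid: bool = True

    @property
    def MD(self) -> float:
        # defined through Dtax/Dtrad so MD == (Dtax + 2*Dtrad)/3 exactly
        return float((self.Dtax + 2.0 * self.Dtrad) / 3.0)

    @property
    def FA(self) -> float:
        return compute_fa(*self.evals)

    @property
    def Dtax(self) -> float:
        return float(self.evals[0])

    @property
    def Dtrad(self) -> float:
        return float((self.evals[1] + self.evals[2]) / 2.0)


@dataclass
class DirectionalIvim:
    """Per-voxel directional IVIM record."""

    Dt_j: np.ndarray
    fp_j: np.ndarray
    Dp_j: np.ndarray
    status_j: np.ndarray
    f: float = np.nan
    Dpax: float = np.nan
    Dprad: float = np.nan
    Dp: float = np.nan
    valid: bool = True
    flags: list = field(default_factory=list)


def compute_fa(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy from eigenvalues (any order, all >= 0)."""
    lam = np.array([l1, l2, l3], dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    ssq = float(lam @ lam)
    if ssq == 0.0:
        return np.nan  # undefined; caller flags
    lbar = lam.mean()
    return float(np.sqrt(1.5 * np.sum((lam - lbar) ** 2) / ssq))


def fit_tensor(d_values, directions) -> TensorFit:
    """Linear LS fit of per-direction diffusivities to a symmetric tensor.

    Requires >= 6 non-coplanar directions.  Negative eigenvalues are clamped
    to 0 and flagged.
    """
    d = np.asarray(d_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    keep = np.isfinite(d)
    if keep.sum() < MIN_DIRECTIONS:
        return TensorFit(np.full((3, 3), np.nan), np.full(3, np.nan), np.full((3, 3), np.nan), valid=False)
    A = tensor_design_matrix(g[keep])
    if np.linalg.matrix_rank(A) < 6:
        return TensorFit(np.full((3, 3), np.nan), np.full(3, np.nan), np.full((3, 3), np.nan), valid=False)
    d6, *_ = np.linalg.lstsq(A, d[keep], rcond=None)
    D = tensor_from_components(d6)
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    clamped = bool(np.any(evals < 0))
    evals = np.clip(evals, 0.0, None)
    return TensorFit(D, evals, evecs, clamped=clamped)


def project_pseudodiffusion(Dp_j, directions, evecs):
    """Constrained pseudodiffusion-tensor amplitudes on the structural frame.

    Solves ``min_{a>=0} || Dp_j - sum_i a_i (g_j . e_i)^2 ||`` and returns
    ``(Dp_ax, Dp_rad, Dp)``; ``Dp = (Dp_ax + 2*Dp_rad)/3`` exactly.  NaN
    entries of ``Dp_j`` (directions with undefined pseudodiffusion) are
    ignored; fewer than :data:`MIN_DIRECTIONS` valid entries invalidates the
    projection and yields NaNs.
    """
    dp = np.asarray(Dp_j, dtype=float)
    g = np.asarray(directions, dtype=float)
    keep = np.isfinite(dp)
    if keep.sum() < MIN_DIRECTIONS:
        return np.nan, np.nan, np.nan
    M = (g[keep] @ np.asarray(evecs)) ** 2  # (ndir, 3): (g.e_i)^2
    a, _ = nnls(M, dp[keep])
    dp_ax = float(a[0])
    dp_rad = float((a[1] + a[2]) / 2.0)
    return dp_ax, dp_rad, float((dp_ax + 2.0 * dp_rad) / 3.0)


def fit_per_direction(series: DwiSeries, mask: np.ndarray):
    """Segmented biexponential fit of every direction's b-curve, per voxel.

    The single b=0 volume is shared across directions.  Returns maps of shape
    ``grid + (ndir,)`` for Dt_j, fp_j, Dp_j and an int8 status map, plus the
    unit direction set (ndir, 3).
    """
    mask = np.asarray(mask).astype(bool)
    sch = series.scheme
    b = sch.b_ms_um2
    nz = b > 0
    dirs = np.unique(np.round(sch.bvecs[nz], 12), axis=0)
    ndir = dirs.shape[0]
    if ndir < MIN_DIRECTIONS:
        raise ValueError(f"need >= {MIN_DIRECTIONS} directions, got {ndir}")
    b0_idx = np.nonzero(~nz)[0]
    shape = series.shape
    out = {
        "Dt_j": np.full(shape + (ndir,), np.nan),
        "fp_j": np.full(shape + (ndir,), np.nan),
        "Dp_j": np.full(shape + (ndir,), np.nan),
        "status_j": np.full(shape + (ndir,), STATUS_FAILED, dtype=np.int8),
    }
    # volume indices per direction, in b order
    dir_cols = []
    for j in range(ndir):
        sel = nz & np.all(np.abs(sch.bvecs - dirs[j]) < 1e-9, axis=1)
        cols = np.nonzero(sel)[0]
        dir_cols.append(cols[np.argsort(b[cols])])
    for idx in zip(*np.nonzero(mask)):
        s0_vals = series.data[idx][b0_idx]
        for j in range(ndir):
            cols = dir_cols[j]
            sig = np.concatenate([s0_vals, series.data[idx][cols]])
            bj = np.concatenate([np.zeros(b0_idx.size), b[cols]])
            fit = fit_voxel(sig, bj)
            out["Dt_j"][idx + (j,)] = fit.Dt
            out["fp_j"][idx + (j,)] = fit.fp
            out["Dp_j"][idx + (j,)] = fit.Dp
            out["status_j"][idx + (j,)] = fit.status
    return out, dirs


def refmap_voxel(Dt_j, fp_j, Dp_j, status_j, dirs) -> tuple[TensorFit, DirectionalIvim]:
    """Tensor + directional-IVIM summary for one voxel's per-direction fits."""
    rec = DirectionalIvim(Dt_j, fp_j, Dp_j, status_j)
    usable = status_j != STATUS_FAILED
    dt = np.where(usable, Dt_j, np.nan)
    tfit = fit_tensor(dt, dirs)
    if not tfit.valid:
        rec.valid = False
        rec.flags.append("insufficient_directions")
        return tfit, rec
    fp_valid = fp_j[usable & np.isfinite(fp_j)]
    rec.f = float(np.median(fp_valid)) if fp_valid.size else np.nan
    dp = np.where(status_j == STATUS_OK, Dp_j, np.nan)
    rec.Dpax, rec.Dprad, rec.Dp = project_pseudodiffusion(dp, dirs, tfit.evecs)
    if not np.isfinite(rec.Dp):
        rec.flags.append("dp_undefined")
    return tfit, rec


def refmap_maps(series: DwiSeries, mask: np.ndarray):
    """All eight REFMAP maps plus QC counters.

    Returns ``(maps, qc)``: maps keyed by :data:`REFMAP_METRICS` plus a
    ``"status"`` int map (0 ok, 2 invalid voxel); qc counts clamped/failed
    voxels.  Voxel failures never abort the run.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("empty mask")
    per_dir, dirs = fit_per_direction(series, mask)
    maps = {k: np.full(series.shape, np.nan) for k in REFMAP_METRICS}
    status = np.full(series.shape, STATUS_FAILED, dtype=np.int8)
    qc = {"n_voxels": int(mask.sum()), "clamped": 0, "tensor_invalid": 0, "dp_undefined": 0}
    for idx in zip(*np.nonzero(mask)):
        tfit, rec = refmap_voxel(
            per_dir["Dt_j"][idx],
            per_dir["fp_j"][idx],
            per_dir["Dp_j"][idx],
            per_dir["status_j"][idx],
            dirs,
        )
        if not tfit.valid:
            qc["tensor_invalid"] += 1
            continue
        if tfit.clamped:
            qc["clamped"] += 1
        maps["MD"][idx] = tfit.MD
        maps["FA"][idx] = tfit.FA
        maps["Dtax"][idx] = tfit.Dtax
        maps["Dtrad"][idx] = tfit.Dtrad
        maps["f"][idx] = rec.f
        maps["Dp"][idx] = rec.Dp
        maps["Dpax"][idx] = rec.Dpax
        maps["Dprad"][idx] = rec.Dprad
        if "dp_undefined" in rec.flags:
            qc["dp_undefined"] += 1
            status[idx] = STATUS_DP_UNDEFINED
        else:
            status[idx] = STATUS_OK
    maps["status"] = status
    return maps, qc
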