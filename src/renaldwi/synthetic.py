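"""Synthetic renal DWI phantom.

Generates a voxel-wise ground truth standing in for a single kidney section:
an elliptical parenchyma with a cortical strip, medullary pyramids whose
principal diffusion axis points radially toward the renal pelvis, and
optional excluded structures (pelvis, cyst) that ROI statistics must skip.

Each acquisition quadrant (gradient waveform x cardiac phase) carries its own
per-tissue parameter distributions.  Default magnitudes follow published
renal values for cardiac-gated bipolar / flow-compensated encoding: the
flow-compensated waveform suppresses the slow (tubular) pseudodiffusion
contribution, lowering fp, while systolic triggering elevates the fast
vascular terms.

Diffusivities are in um^2/ms throughout; b-values are converted to ms/um^2
inside the signal synthesis so that b*D is dimensionless (b = 800 s/mm2 is
b = 0.8 ms/um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AcquisitionScheme, DwiSeries, MaskSet

LABEL_BACKGROUND = 0
LABEL_CORTEX = 1
LABEL_MEDULLA = 2
LABEL_EXCLUDED = 3


class ConfigurationError(ValueError):
    """Inconsistent phantom or cohort configuration."""


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue, per-quadrant generative distribution (mean, SD).

    The structural tensor is axially symmetric with eigenvalues derived from
    the (MD, FA) pair; the pseudodiffusion tensor shares the eigenframe with
    axial/radial eigenvalues ``dp*(1+2*pseudo_aniso)`` / ``dp*(1-pseudo_aniso)``.
    """

    md: float
    md_sd: float
    fa: float
    fa_sd: float
    fp: float
    fp_sd: float
    dp: float
    dp_sd: float
    pseudo_aniso: float = 0.05

    def validate(self) -> None:
        if self.md <= 0 or self.dp <= 0:
            raise ConfigurationError("diffusivities must be positive")
        if not 0.0 <= self.fp <= 1.0:
            raise ConfigurationError("fp must lie in [0, 1]")
        if not 0.0 <= self.fa < 1.0:
            raise ConfigurationError("FA target must lie in [0, 1)")
        if not 0.0 <= self.pseudo_aniso < 0.5:
            raise ConfigurationError("pseudo_aniso must lie in [0, 0.5)")


# Default generative magnitudes per quadrant and tissue: renal cortex/medulla
# means (SD) for cardiac-gated bipolar and flow-compensated encoding.
DEFAULT_TISSUE_PARAMS: dict[tuple[str, str], dict[str, TissueParams]] = {
    ("bipolar", "diastole"): {
        "cortex": TissueParams(1.96, 0.09, 0.19, 0.07, 0.16, 0.04, 25.40, 10.28, 0.05),
        "medulla": TissueParams(1.89, 0.10, 0.28, 0.06, 0.20, 0.05, 50.89, 20.26, 0.30),
    },
    ("bipolar", "systole"): {
        "cortex": TissueParams(2.08, 0.24, 0.21, 0.05, 0.21, 0.07, 28.95, 15.36, 0.05),
        "medulla": TissueParams(1.98, 0.24, 0.29, 0.05, 0.21, 0.06, 57.27, 27.84, 0.30),
    },
    ("flow_compensated", "diastole"): {
        "cortex": TissueParams(1.90, 0.08, 0.10, 0.03, 0.08, 0.02, 34.25, 18.76, 0.05),
        "medulla": TissueParams(1.84, 0.08, 0.16, 0.05, 0.10, 0.03, 40.05, 22.10, 0.30),
    },
    ("flow_compensated", "systole"): {
        "cortex": TissueParams(2.05, 0.10, 0.13, 0.03, 0.11, 0.04, 31.74, 18.14, 0.05),
        "medulla": TissueParams(1.93, 0.08, 0.18, 0.04, 0.11, 0.04, 50.11, 24.00, 0.30),
    },
}

#: Fluid-like parameters for excluded structures (cyst / pelvis).
FLUID_PARAMS = TissueParams(3.0, 0.05, 0.02, 0.01, 0.0, 0.0, 20.0, 1.0, 0.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry + generative distributions for :func:`make_phantom`."""

    shape: tuple[int, int, int] = (32, 32, 3)
    semi_axes: tuple[float, float] = (13.0, 9.0)  # in-plane ellipse, voxels
    cortex_thickness: float = 0.25  # fraction of normalized ellipse radius
    n_pyramids: int = 6
    pyramid_fill: float = 0.7  # angular fraction of each sector that is medulla
    pelvis_radius: float = 0.15  # normalized radius of excluded central pelvis
    cyst_center: tuple[int, int, int] | None = None
    cyst_radius: float = 0.0  # voxels; 0 disables
    s0_mean: float = 1000.0
    s0_sd: float = 15.0
    tissue_params: dict = field(
        default_factory=lambda: {
            q: dict(t) for q, t in DEFAULT_TISSUE_PARAMS.items()
        }
    )
    noise_sigma: float = 0.0  # Rician sigma, absolute signal units
    seed: int = 0

    def validate(self) -> None:
        a, b = self.semi_axes
        nx, ny, _nz = self.shape
        if a <= 0 or b <= 0:
            raise ConfigurationError("ellipse semi-axes must be positive")
        if 2 * a >= nx or 2 * b >= ny:
            raise ConfigurationError(
                "kidney ellipse does not fit inside the grid (pyramids outside grid)"
            )
        if not 0 < self.cortex_thickness < 1:
            raise ConfigurationError("cortex_thickness must be in (0, 1)")
        if self.pelvis_radius >= 1 - self.cortex_thickness:
            raise ConfigurationError("pelvis overlaps the cortical strip")
        if self.n_pyramids < 1:
            raise ConfigurationError("need at least one medullary pyramid")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        for quad, tissues in self.tissue_params.items():
            for tp in tissues.values():
                tp.validate()
                lam1 = _eigs_from_md_fa(tp.md, tp.fa)[0]
                if tp.dp * (1 - tp.pseudo_aniso) <= lam1:
                    raise ConfigurationError(
                        f"pseudodiffusion eigenvalues must exceed the largest "
                        f"tissue eigenvalue (quadrant {quad})"
                    )


def _eigs_from_md_fa(md: float, fa: float) -> tuple[float, float]:
    """Axially symmetric eigenvalues (l1, l_rad) with the requested MD and FA.

    With l1 = md*(1+2d), l2 = l3 = md*(1-d), FA = 3d/sqrt(3+6d^2), hence
    d = fa*sqrt(3/(9-6 fa^2)).
    """
    d = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    return md * (1.0 + 2.0 * d), md * (1.0 - d)


@dataclass
class QuadrantTruth:
    """Voxel-wise ground truth for one acquisition quadrant."""

    S0: np.ndarray  # (x, y, z)
    evals: np.ndarray  # (x, y, z, 3) structural eigenvalues, descending
    fp: np.ndarray  # (x, y, z)
    pevals: np.ndarray  # (x, y, z, 3) pseudodiffusion eigenvalues

    def md(self) -> np.ndarray:
        return self.evals.mean(axis=-1)

    def fa(self) -> np.ndarray:
        lam = self.evals
        lbar = lam.mean(axis=-1, keepdims=True)
        num = np.sum((lam - lbar) ** 2, axis=-1)
        den = np.sum(lam**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(1.5 * num / den)


@dataclass
class GroundTruthMaps:
    """Phantom ground truth: label map, shared eigenframe, per-quadrant maps."""

    labels: np.ndarray  # int8 (x, y, z)
    evecs: np.ndarray  # (x, y, z, 3, 3); column i is eigenvector e_i
    quadrants: dict[tuple[str, str], QuadrantTruth]
    voxel_size: tuple[float, float, float] = (2.2, 2.2, 5.0)

    def mask_set(self) -> MaskSet:
        cortex = self.labels == LABEL_CORTEX
        medulla = self.labels == LABEL_MEDULLA
        return MaskSet(
            parenchyma=cortex | medulla,
            cortex=cortex,
            medulla=medulla,
            excluded=self.labels == LABEL_EXCLUDED,
        )


def _radial_frame(shape, center) -> np.ndarray:
    """Per-voxel orthonormal frame: e1 radial in-plane (toward the pelvis),
    e2 tangential, e3 through-plane."""
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = x - center[0]
    dy = y - center[1]
    norm = np.hypot(dx, dy)
    ux = np.where(norm > 0, dx / np.where(norm > 0, norm, 1.0), 1.0)
    uy = np.where(norm > 0, dy / np.where(norm > 0, norm, 1.0), 0.0)
    evecs = np.zeros((nx, ny, nz, 3, 3))
    evecs[..., 0, 0] = ux[..., None]
    evecs[..., 1, 0] = uy[..., None]
    evecs[..., 0, 1] = -uy[..., None]
    evecs[..., 1, 1] = ux[..., None]
    evecs[..., 2, 2] = 1.0
    return evecs


def make_phantom(config: PhantomConfig) -> GroundTruthMaps:
    """Build the voxel-wise ground truth for every acquisition quadrant.

    Deterministic under ``config.seed``: repeated calls with an identical
    config are bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    a, b = config.semi_axes

    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rho2d = np.sqrt(((x - cx) / a) ** 2 + ((y - cy) / b) ** 2)
    theta2d = np.arctan2(y - cy, x - cx)
    rho = np.repeat(rho2d[:, :, None], nz, axis=2)
    theta = np.repeat(theta2d[:, :, None], nz, axis=2)

    labels = np.full(config.shape, LABEL_BACKGROUND, dtype=np.int8)
    inside = rho <= 1.0
    labels[inside] = LABEL_CORTEX
    # medullary pyramids: angular wedges of the inner region; inter-pyramid
    # gaps stay cortical (columns of Bertin)
    inner = inside & (rho < 1.0 - config.cortex_thickness) & (rho > config.pelvis_radius)
    sector = np.mod(theta, 2 * np.pi / config.n_pyramids) * config.n_pyramids / (2 * np.pi)
    in_pyramid = np.abs(sector - 0.5) <= config.pyramid_fill / 2.0
    labels[inner & in_pyramid] = LABEL_MEDULLA
    labels[inside & (rho <= config.pelvis_radius)] = LABEL_EXCLUDED
    if config.cyst_radius > 0 and config.cyst_center is not None:
        ccx, ccy, ccz = config.cyst_center
        z = np.arange(nz)[None, None, :]
        dist = np.sqrt(
            (x[..., None] - ccx) ** 2 + (y[..., None] - ccy) ** 2 + (z - ccz) ** 2
        )
        labels[(dist <= config.cyst_radius) & inside] = LABEL_EXCLUDED

    evecs = _radial_frame(config.shape, (cx, cy))

    quadrants: dict[tuple[str, str], QuadrantTruth] = {}
    for quad in sorted(config.tissue_params):
        tissues = config.tissue_params[quad]
        S0 = np.zeros(config.shape)
        evals = np.zeros(config.shape + (3,))
        fp = np.zeros(config.shape)
        pevals = np.zeros(config.shape + (3,))
        for label, tp in (
            (LABEL_CORTEX, tissues["cortex"]),
            (LABEL_MEDULLA, tissues["medulla"]),
            (LABEL_EXCLUDED, FLUID_PARAMS),
        ):
            sel = labels == label
            n = int(sel.sum())
            if n == 0:
                continue
            S0[sel] = np.clip(rng.normal(config.s0_mean, config.s0_sd, n), 1.0, None)
            md = np.clip(rng.normal(tp.md, tp.md_sd, n), 0.2, None)
            fa = np.clip(rng.normal(tp.fa, tp.fa_sd, n), 0.0, 0.92)
            l1, lrad = _eigs_from_md_fa(md, fa)
            evals[sel] = np.stack([l1, lrad, lrad], axis=-1)
            fp[sel] = np.clip(rng.normal(tp.fp, tp.fp_sd, n), 0.0, 0.7)
            dp = rng.normal(tp.dp, tp.dp_sd, n)
            dp_floor = 1.05 * l1 / max(1.0 - tp.pseudo_aniso, 0.5)
            dp = np.maximum(dp, np.maximum(dp_floor, 5.0))
            pevals[sel] = np.stack(
                [
                    dp * (1.0 + 2.0 * tp.pseudo_aniso),
                    dp * (1.0 - tp.pseudo_aniso),
                    dp * (1.0 - tp.pseudo_aniso),
                ],
                axis=-1,
            )
        quadrants[quad] = QuadrantTruth(S0, evals, fp, pevals)
    return GroundTruthMaps(labels, evecs, quadrants)


def projected_diffusivity(evals: np.ndarray, evecs: np.ndarray, g: np.ndarray) -> np.ndarray:
    """g^T D g per voxel for a field of eigen-decomposed tensors."""
    proj = np.einsum("...ci,c->...i", evecs, g)  # g . e_i
    return np.einsum("...i,...i->...", evals, proj**2)


def synthesize_dwi(
    maps: GroundTruthMaps,
    scheme: AcquisitionScheme,
    sigma: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DwiSeries:
    """Forward-model the DWI signal for the scheme's quadrant.

    Noiseless signal per voxel and volume:
    ``S = S0 * [fp exp(-b g'Dp g) + (1-fp) exp(-b g'Dt g)]`` with b in
    ms/um^2.  At b=0 the signal equals S0 exactly.  With ``sigma > 0``,
    Rician (magnitude) noise is applied:
    ``sqrt((S + sigma*N1)^2 + (sigma*N2)^2)``.
    """
    if scheme.quadrant not in maps.quadrants:
        raise ConfigurationError(
            f"phantom has no ground truth for quadrant {scheme.quadrant}"
        )
    if sigma is None:
        sigma = 0.0
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    truth = maps.quadrants[scheme.quadrant]
    b_all = scheme.b_ms_um2
    shape = maps.labels.shape
    signal = np.zeros(shape + (len(scheme),))
    tissue = maps.labels != LABEL_BACKGROUND
    for v in range(len(scheme)):
        bv = b_all[v]
        if bv == 0:
            signal[..., v] = truth.S0
        else:
            g = scheme.bvecs[v]
            dt_g = projected_diffusivity(truth.evals, maps.evecs, g)
            dp_g = projected_diffusivity(truth.pevals, maps.evecs, g)
            signal[..., v] = truth.S0 * (
                truth.fp * np.exp(-bv * dp_g)
                + (1.0 - truth.fp) * np.exp(-bv * dt_g)
            )
        signal[..., v] *= tissue
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DwiSeries(signal, scheme, voxel_size=maps.voxel_size)


def scaled_tissue_params(
    base: dict,
    md_scale: float = 1.0,
    fa_scale: float = 1.0,
    fp_scale: float = 1.0,
    dp_scale: float = 1.0,
) -> dict:
    """Multiplicatively rescale a per-quadrant tissue parameter table
    (used to derive per-kidney phantoms from the population defaults)."""
    out = {}
    for quad, tissues in base.items():
        out[quad] = {
            name: replace(
                tp,
                md=tp.md * md_scale,
                fa=min(tp.fa * fa_scale, 0.95),
                fp=min(tp.fp * fp_scale, 1.0),
                dp=tp.dp * dp_scale,
            )
            for name, tp in tissues.items()
        }
    return out
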