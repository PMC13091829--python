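"""Reading, writing and validation of DWI artifacts.

Formats: NIfTI-1 volumes (via nibabel), FSL-dialect ``.bval``/``.bvec`` text
gradient tables (b in s/mm2 on one row; three rows of direction components),
TSV subject tables and YAML run configs.  A small JSON sidecar carries the
cardiac-gating quadrant tag (gradient waveform x cardiac phase) that NIfTI
has no standard slot for.

All geometry is voxel-index space (0-based); masks are voxel-aligned to the
DWI grid and left/right kidneys are handled as separate files and runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: b-value menu of the emulated protocol, s/mm2.
STUDY_BVALUES_S_MM2 = (0, 10, 30, 50, 70, 80, 100, 120, 200, 400, 600, 800)

WAVEFORMS = ("bipolar", "flow_compensated")
PHASES = ("systole", "diastole")
#: The four acquisition quadrants: gradient waveform x cardiac phase.
QUADRANTS = tuple((w, p) for w in WAVEFORMS for p in PHASES)


class FormatError(ValueError):
    """A file or table violates the expected format or an invariant."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Gradient table plus the cardiac-gating quadrant tag.

    bvals are stored in s/mm2 as acquired; model code uses :attr:`b_ms_um2`
    (b/1000) so that b*D is dimensionless for diffusivities in um^2/ms.
    """

    bvals: np.ndarray  # (nvol,), s/mm2
    bvecs: np.ndarray  # (nvol, 3), unit vectors for b>0
    waveform: str = "bipolar"
    phase: str = "diastole"

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.shape != (bvals.size, 3):
            raise FormatError(
                f"bvec shape {bvecs.shape} does not match {bvals.size} volumes"
            )
        if np.any(bvals < 0):
            raise FormatError("negative b-value in scheme")
        if not np.any(bvals == 0):
            raise FormatError("scheme must contain at least one b=0 volume")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise FormatError("non-unit gradient direction at nonzero b")
        if self.waveform not in WAVEFORMS:
            raise FormatError(f"unknown waveform {self.waveform!r}")
        if self.phase not in PHASES:
            raise FormatError(f"unknown phase {self.phase!r}")

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms/um^2 (s/mm2 divided by 1000)."""
        return self.bvals / 1000.0

    @property
    def quadrant(self) -> tuple[str, str]:
        return (self.waveform, self.phase)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def unique_nonzero_b(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])

    @classmethod
    def study_scheme(
        cls,
        waveform: str = "bipolar",
        phase: str = "diastole",
        directions: np.ndarray | None = None,
    ) -> "AcquisitionScheme":
        """The emulated protocol: one b=0 volume, then 11 nonzero b-values
        (10..800 s/mm2) each along 12 directions -> 133 volumes."""
        from .directions import DIRECTIONS_12

        dirs = DIRECTIONS_12 if directions is None else np.asarray(directions)
        bvals = [0.0]
        bvecs = [np.zeros(3)]
        for b in STUDY_BVALUES_S_MM2[1:]:
            for g in dirs:
                bvals.append(float(b))
                bvecs.append(g)
        return cls(np.array(bvals), np.array(bvecs), waveform, phase)


@dataclass
class DwiSeries:
    """A 4D DWI acquisition bound to its scheme (one quadrant)."""

    data: np.ndarray  # (x, y, z, nvol)
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float] = (2.2, 2.2, 5.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError("DWI data must be 4D (x, y, z, volume)")
        if self.data.shape[3] != len(self.scheme):
            raise FormatError(
                f"{self.data.shape[3]} volumes but scheme lists {len(self.scheme)}"
            )
        if np.any(self.data < 0):
            raise FormatError("negative signal values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MaskSet:
    """Tissue masks aligned to a DWI grid.

    ``excluded`` marks non-parenchymal voxels (lesion, cyst, renal pelvis,
    vessels) that must never contribute to ROI statistics.
    """

    parenchyma: np.ndarray
    cortex: np.ndarray
    medulla: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.parenchyma = np.asarray(self.parenchyma).astype(bool)
        self.cortex = np.asarray(self.cortex).astype(bool)
        self.medulla = np.asarray(self.medulla).astype(bool)
        if self.excluded is None:
            self.excluded = np.zeros_like(self.parenchyma)
        self.excluded = np.asarray(self.excluded).astype(bool)
        self.validate()

    def validate(self) -> None:
        if np.any(self.cortex & self.medulla):
            raise FormatError("cortex and medulla masks overlap")
        if np.any((self.cortex | self.medulla) & ~self.parenchyma):
            raise FormatError("cortex/medulla extend outside parenchyma")
        if np.any(self.excluded & self.parenchyma):
            raise FormatError("excluded labels overlap parenchyma")

    def tissue(self, name: str) -> np.ndarray:
        try:
            m = getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown tissue {name!r}") from None
        return m & ~self.excluded


# ---------------------------------------------------------------------------
# NIfTI + gradient-table round trip

def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_series(series: DwiSeries, basename: str | Path) -> dict[str, Path]:
    """Write ``<basename>.nii.gz``, ``.bval``, ``.bvec`` and a ``.json``
    sidecar with the quadrant tag.  Returns the written paths."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    paths = {
        "nii": base.with_suffix(".nii.gz"),
        "bval": base.with_suffix(".bval"),
        "bvec": base.with_suffix(".bvec"),
        "json": base.with_suffix(".json"),
    }
    nib.save(img, paths["nii"])
    sch = series.scheme
    paths["bval"].write_text(
        " ".join(format(b, "g") for b in sch.bvals) + "\n"
    )
    rows = [" ".join(format(v, ".10g") for v in sch.bvecs[:, ax]) for ax in range(3)]
    paths["bvec"].write_text("\n".join(rows) + "\n")
    paths["json"].write_text(
        json.dumps(
            {
                "waveform": sch.waveform,
                "phase": sch.phase,
                "voxel_size": list(series.voxel_size),
            },
            indent=1,
        )
    )
    return paths


def read_series(basename: str | Path) -> DwiSeries:
    """Read a series written by :func:`write_series` (or any NIfTI plus
    FSL-style bval/bvec triple sharing a basename)."""
    base = Path(basename)
    nii = base.with_suffix(".nii.gz")
    if not nii.exists():
        nii = base.with_suffix(".nii")
    if not nii.exists():
        raise FormatError(f"no NIfTI found for {base}")
    data = np.asarray(nib.load(nii).dataobj, dtype=np.float32)
    bval_path, bvec_path = base.with_suffix(".bval"), base.with_suffix(".bvec")
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FormatError(f"missing gradient table file {p}")
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path} must have 3 rows")
    if bvals.size != bvecs.shape[1]:
        raise FormatError(
            f"{bval_path} lists {bvals.size} b-values but {bvec_path} has "
            f"{bvecs.shape[1]} columns"
        )
    if data.ndim != 4 or data.shape[3] != bvals.size:
        raise FormatError(
            f"{nii} volume count {data.shape[-1] if data.ndim == 4 else 'n/a'} "
            f"does not match {bval_path}"
        )
    meta = {}
    if base.with_suffix(".json").exists():
        meta = json.loads(base.with_suffix(".json").read_text())
    try:
        scheme = AcquisitionScheme(
            bvals,
            bvecs.T,
            waveform=meta.get("waveform", "bipolar"),
            phase=meta.get("phase", "diastole"),
        )
    except FormatError as exc:
        raise FormatError(f"{bvec_path}: {exc}") from None
    vs = tuple(meta.get("voxel_size", (2.2, 2.2, 5.0)))
    return DwiSeries(data, scheme, voxel_size=vs)


def write_mask(mask: np.ndarray, path: str | Path, voxel_size=(2.2, 2.2, 5.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _affine(voxel_size))
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj).astype(bool)


# ---------------------------------------------------------------------------
# Subject table

SUBJECT_COLUMNS = [
    "subject_id",
    "side",
    "volume_ml",
    "eGFR",
    "mGFR",
    "mGFRt",
    "SRF",
    "proteinuria",
]


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-kidney subject TSV.

    One row per (subject, side).  ``mGFR``/``mGFRt`` are subject totals;
    split values are obtained downstream by multiplying with ``SRF``.
    SRF pairs must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subject table missing column(s): {', '.join(missing)}")
    if not df["side"].isin(["L", "R"]).all():
        raise FormatError("side must be 'L' or 'R'")
    if (df["volume_ml"] <= 0).any():
        raise FormatError("kidney volumes must be positive")
    if not df["proteinuria"].isin([0, 1]).all():
        raise FormatError("proteinuria must be 0/1")
    srf_sum = df.groupby("subject_id")["SRF"].sum()
    both = df.groupby("subject_id")["side"].nunique()
    bad = srf_sum[(both == 2) & (np.abs(srf_sum - 1.0) > 1e-6)]
    if len(bad):
        raise FormatError(
            f"SRF pair does not sum to 1 for subject(s): {', '.join(map(str, bad.index))}"
        )
    return df


def write_subject_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Run configs

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path} is not a YAML mapping")
    return cfg


def dump_config(cfg: dict, out_dir: str | Path, name: str = "run_config.yaml") -> Path:
    """Version the effective config into the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
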