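"""Directional REFMAP fitting: per-direction IVIM, tensor metrics, and
pseudodiffusion projected onto the structural eigenframe.

Uses a small noiseless phantom so the eight output maps can be compared
voxel-wise against the generative ground truth.
"""

import numpy as np

from renaldwi import AcquisitionScheme, PhantomConfig, make_phantom, synthesize_dwi
from renaldwi.refmap import refmap_maps
from renaldwi.synthetic import TissueParams

params = {
    ("bipolar", "diastole"): {
        "cortex": TissueParams(1.96, 0.05, 0.19, 0.03, 0.16, 0.02, 25.4, 2.0, 0.05),
        "medulla": TissueParams(1.89, 0.05, 0.28, 0.03, 0.20, 0.02, 50.89, 5.0, 0.30),
    }
}
cfg = PhantomConfig(shape=(16, 16, 1), semi_axes=(6.5, 4.5), tissue_params=params, seed=3)
truth = make_phantom(cfg)
masks = truth.mask_set()
series = synthesize_dwi(truth, AcquisitionScheme.study_scheme("bipolar", "diastole"), 0.0)

mask = masks.tissue("cortex") | masks.tissue("medulla")
maps, qc = refmap_maps(series, mask)
print(f"fitted {qc['n_voxels']} voxels; QC: {qc}")

q = truth.quadrants[("bipolar", "diastole")]
truth_maps = {
    "MD": q.md(), "FA": q.fa(),
    "Dtax": q.evals[..., 0], "Dtrad": q.evals[..., 1:].mean(-1),
    "f": q.fp, "Dp": q.pevals.mean(-1),
    "Dpax": q.pevals[..., 0], "Dprad": q.pevals[..., 1:].mean(-1),
}
print(f"\n{'metric':>6} {'fitted':>8} {'truth':>8} {'max rel err':>12}")
for name, tr in truth_maps.items():
    rel = np.abs(maps[name][mask] - tr[mask]) / np.abs(tr[mask])
    print(f"{name:>6} {np.nanmean(maps[name][mask]):8.3f} {tr[mask].mean():8.3f} "
          f"{np.nanmax(rel):12.2e}")

med, cor = masks.tissue("medulla"), masks.tissue("cortex")
print(
    f"\nmedulla FA {np.nanmean(maps['FA'][med]):.2f} > cortex FA "
    f"{np.nanmean(maps['FA'][cor]):.2f}: the radially oriented pyramids are"
    "\nanisotropic, the cortical strip nearly isotropic. On noiseless data"
    "\nevery map recovers its ground truth to better than 1%."
)
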