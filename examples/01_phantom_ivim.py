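"""Build a kidney phantom, synthesize cardiac-gated DWI, fit scalar IVIM.

Generates the default two-tissue phantom (cortical strip + medullary
pyramids), forward-models the 133-volume bipolar/diastole acquisition with
Rician noise, fits the segmented biexponential to the direction-averaged
signals, and compares ROI means with the configured ground truth.
"""

import numpy as np

from renaldwi import AcquisitionScheme, PhantomConfig, make_phantom, synthesize_dwi
from renaldwi.ivim import fit_voxelwise_average
from renaldwi.roi import summarize_roi

cfg = PhantomConfig(seed=0)
truth = make_phantom(cfg)
masks = truth.mask_set()
scheme = AcquisitionScheme.study_scheme("bipolar", "diastole")
series = synthesize_dwi(truth, scheme, sigma=10.0, seed=1)  # SNR(b0) ~ 100
print(f"synthesized {series.data.shape} volumes at b = {sorted(set(scheme.bvals))}")

mask = masks.tissue("cortex") | masks.tissue("medulla")
maps = fit_voxelwise_average(series, mask)

q = truth.quadrants[("bipolar", "diastole")]
for tissue in ("cortex", "medulla"):
    roi = summarize_roi(maps, masks, tissue)
    t = masks.tissue(tissue)
    print(f"\n{tissue} ({roi['Dt'][1]} voxels)")
    print(f"  Dt fitted {roi['Dt'][0]:.3f}  (ground-truth MD {q.md()[t].mean():.3f}) um^2/ms")
    print(f"  fp fitted {roi['fp'][0]:.3f}  (ground truth  {q.fp[t].mean():.3f})")
    print(f"  Dp fitted {roi['Dp'][0]:.1f}   (ground truth  {q.pevals.mean(-1)[t].mean():.1f}) um^2/ms")

print(
    "\nFitted ROI means track the configured tissue magnitudes; the small Dt"
    "\noffset from MD is the expected effect of direction-averaging an"
    "\nanisotropic signal before the biexponential fit."
)
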