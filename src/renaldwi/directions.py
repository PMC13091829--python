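"""Fixed diffusion gradient direction sets.

The study protocol acquires 12 noncollinear directions per shell. The exact
table is scanner-specific and not standardized, so this package ships a fixed
12-direction set obtained by electrostatic (Coulomb) repulsion of 12 antipodal
point pairs on the unit sphere.  Antipodal energy of the frozen set is 102.087;
the minimum inter-axis angle is 38.1 degrees and the condition number of the
resulting diffusion-tensor design matrix is 1.58, so all 6 unique tensor
components are well determined.
"""

from __future__ import annotations

import numpy as np

# Electrostatic-repulsion set, canonicalized to the upper hemisphere and
# lexicographically sorted.  Frozen; do not re-optimize.
DIRECTIONS_12 = np.array(
    [
        [-0.475559249380709, 0.879141958339318, 0.030867740697451],
        [-0.444398395822012, -0.887003987782476, 0.125435208170626],
        [-0.991519515012037, 0.027136291340904, 0.127093166781524],
        [0.808308987182606, -0.452602376888526, 0.376547035142606],
        [0.773730869702957, 0.497873646336740, 0.391742738990864],
        [0.006114805236544, 0.881397524646502, 0.472335699163145],
        [-0.722931381472268, -0.419043747024393, 0.549338289000825],
        [0.105898448564555, -0.793352103619239, 0.599481407780549],
        [-0.653339729659635, 0.423991332209335, 0.627198969912761],
        [0.555710698066437, -0.039980963253113, 0.830413838174597],
        [0.021480303013909, 0.389029775751834, 0.920974717438491],
        [-0.188772330968325, -0.262535170978648, 0.946277068865138],
    ],
    dtype=float,
)
DIRECTIONS_12.setflags(write=False)


def tensor_design_matrix(directions: np.ndarray) -> np.ndarray:
    """Rows ``[gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]`` mapping the 6
    unique components of a symmetric tensor D to the projections g^T D g."""
    g = np.asarray(directions, dtype=float)
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2.0 * g[:, 0] * g[:, 1],
            2.0 * g[:, 0] * g[:, 2],
            2.0 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_from_components(d6: np.ndarray) -> np.ndarray:
    """Assemble the symmetric 3x3 tensor from [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    dxx, dyy, dzz, dxy, dxz, dyz = d6
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
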