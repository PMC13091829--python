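import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renaldwi.io import AcquisitionScheme
from renaldwi.synthetic import PhantomConfig, TissueParams, make_phantom, synthesize_dwi

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def identifiable_tissue_params():
    """Generative parameters kept inside the segmented fit's identifiable
    regime (fp >= 0.05 and Dp >= 5*Dt per direction), for round-trip tests."""
    return {
        ("bipolar", "diastole"): {
            "cortex": TissueParams(1.96, 0.05, 0.19, 0.03, 0.16, 0.02, 25.4, 2.0, 0.05),
            "medulla": TissueParams(1.89, 0.05, 0.28, 0.03, 0.20, 0.02, 50.89, 5.0, 0.30),
        }
    }


@pytest.fixture(scope="session")
def study_scheme():
    return AcquisitionScheme.study_scheme("bipolar", "diastole")


@pytest.fixture(scope="session")
def small_phantom():
    """Small anisotropic phantom in the identifiable regime (one quadrant)."""
    cfg = PhantomConfig(
        shape=(16, 16, 1),
        semi_axes=(6.5, 4.5),
        tissue_params=identifiable_tissue_params(),
        seed=3,
    )
    return cfg, make_phantom(cfg)


@pytest.fixture(scope="session")
def noiseless_series(small_phantom, study_scheme):
    _, maps = small_phantom
    return synthesize_dwi(maps, study_scheme, 0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
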