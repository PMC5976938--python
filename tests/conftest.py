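import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import cartiqmap as cq

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return cq.calibrate_default_profiles()


@pytest.fixture(scope="session")
def flat_spec():
    return cq.PhantomSpec(
        width_mm=15.0, thickness_mm=3.0, curvature_per_m=0.0,
        pixel_spacing_mm=0.1, snr=np.inf, seed=0,
    )


@pytest.fixture(scope="session")
def flat_sample(flat_spec):
    return cq.make_geometry(flat_spec)


@pytest.fixture(scope="session")
def curved_spec():
    return cq.PhantomSpec(snr=np.inf, seed=0)


@pytest.fixture(scope="session")
def curved_sample(curved_spec):
    return cq.make_geometry(curved_spec)


@pytest.fixture(scope="session")
def curved_phantom(curved_spec, curved_sample, default_model):
    gt = cq.make_ground_truth(curved_sample, default_model, curved_spec)
    return curved_sample, gt


@pytest.fixture(scope="session")
def small_config(tmp_path_factory):
    """Reduced phantom for fast end-to-end runs."""
    out = tmp_path_factory.mktemp("run")
    return cq.RunConfig(
        width_mm=8.0, thickness_mm=1.6, pixel_spacing_mm=0.2,
        cr_width_mm=4.0, snr=50.0, seed=17, out_dir=str(out),
    )
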