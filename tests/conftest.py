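import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mionmap.hemodynamics as hemodynamics
import mionmap.phantom_sim as phantom_sim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return phantom_sim.make_phantom()


@pytest.fixture(scope="session")
def small_atlas():
    return phantom_sim.make_phantom(phantom_sim.VolumeGrid((16, 16, 12)))


@pytest.fixture(scope="session")
def catalog():
    return phantom_sim.default_catalog()


@pytest.fixture(scope="session")
def rf():
    return hemodynamics.mion_rf()


@pytest.fixture(scope="session")
def design(catalog):
    return phantom_sim.make_run_design(20, catalog=catalog)


@pytest.fixture(scope="session")
def noise_free_truth():
    """Planted amplitudes with no noise, drift or nuisance."""
    return phantom_sim.GroundTruth(
        amplitudes={"A1-like": {"*": 1.0}, "F5-like": {"coos": 0.5, "barks": -0.5}},
        ar1_rho=0.0,
        white_sd_pct=0.0,
        drift_coeffs_pct=(0.0,),
        n_white_components=0,
        n_csf_components=0,
        nuisance_sd_pct=0.0,
    )


@pytest.fixture(scope="session")
def simulated_run(atlas, design, rf, catalog):
    """One default-truth run shared by read-only tests."""
    truth = phantom_sim.default_truth(catalog)
    img, record = phantom_sim.simulate_run(atlas, design, truth, rf, seed=20)
    return img, record, truth
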