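import numpy as np
import pytest

from hiquant.synthetic import EphysSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless phantom with degenerate (zero-spread) class T2s."""
    spec = PhantomSpec(
        noise_sigma=0.0,
        class_t2_sd={"uninjured": 0.0, "penumbra": 0.0, "core": 0.0},
        seed=11,
    )
    vol, truth, lesion = make_phantom(spec)
    return spec, vol, truth, lesion


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study conditions: Rician noise at 2% of S0 (SNR 50)."""
    spec = PhantomSpec(seed=23, lost_fraction=0.08)
    vol, truth, lesion = make_phantom(spec)
    return spec, vol, truth, lesion


@pytest.fixture
def quiet_ephys_spec():
    """Fully deterministic sweeps: no recording noise, no slice variability."""
    return EphysSpec(noise_sd_mv=0.0, amplitude_cv=0.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
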