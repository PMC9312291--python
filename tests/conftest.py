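import numpy as np
import pytest

from fmripattern import synth


@pytest.fixture(scope="session")
def paper_design():
    """Default acquisition design plus per-run event tables."""
    return synth.build_design()


@pytest.fixture(scope="session")
def small_atlas():
    return synth.default_atlas((12, 12, 10))


@pytest.fixture(scope="session")
def quiet_noise():
    return synth.NoiseSpec(
        white_sd=0.0, ar1_rho=0.0, drift_amplitude=0.0,
        n_drift_components=0, motion_coupling=0.0,
    )


@pytest.fixture(scope="session")
def realistic_noise():
    return synth.NoiseSpec(
        white_sd=1.0, ar1_rho=0.3, drift_amplitude=1.0,
        n_drift_components=3, motion_coupling=0.1,
    )
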