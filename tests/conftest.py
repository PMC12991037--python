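import numpy as np
import pytest

from cnetvna import synthdata


@pytest.fixture(scope="session")
def bright_stream():
    """One molecule, no bleaching, ~2e4 photons, 2% background."""
    stream, truth = synthdata.simulate_photon_stream(
        true_tau=3.5, seed=1, bleach_rate=0.0, duration=1.0, background_rate=408.0
    )
    return stream, truth


@pytest.fixture(scope="session")
def tilted_trajectory():
    """Rigid 12 bp duplex at a fixed 60 degree tilt, 5 frames."""
    return synthdata.simulate_trajectory(
        n_bp=12, n_frames=5, tilt_distribution=(60.0, 0.0), seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
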