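import numpy as np
import pytest

from gazeflow import retflow, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coarse_spec():
    """Reduced retinal grid for fast unit tests (full default resolution is
    exercised in the acceptance suite)."""
    return retflow.RetinalGridSpec(fov_deg=45.0, spacing_deg=1.5)


@pytest.fixture(scope="session")
def aligned_approach():
    """Short straight approach with fixation on the ground track."""
    return synth.straight_approach(duration=0.4, fps=30)


@pytest.fixture(scope="session")
def aligned_features(aligned_approach, coarse_spec):
    df, frames = retflow.analyze_scenario(
        aligned_approach, spec=coarse_spec, ground_spacing=0.4, keep_frames=True
    )
    return df, frames
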