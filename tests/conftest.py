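import numpy as np
import pytest

from memims import synthgen


@pytest.fixture(scope="session")
def small_membrane():
    """Membrane with planted 23-lipid shell (10/13), transients and clashes."""
    traj, gt = synthgen.gen_membrane(
        n_lipids=70, box=(100.0, 100.0, 80.0), n_frames=5,
        n_transient=4, n_clashes=2, seed=42,
    )
    return traj, gt


@pytest.fixture(scope="session")
def flat_membrane():
    traj, gt = synthgen.gen_membrane(
        n_lipids=60, box=(80.0, 80.0, 80.0), n_frames=3, n_transient=0,
        n_clashes=0, seed=7,
    )
    return traj, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
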