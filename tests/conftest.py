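import numpy as np
import pytest

from skimocap import DEFAULT_SKELETON, PoseFrame, generate_reference_run


@pytest.fixture(scope="session")
def skeleton():
    return DEFAULT_SKELETON


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def reference_run():
    """Default giant-slalom reference run with closed-form ground truth."""
    return generate_reference_run()


def random_pose(rng: np.random.Generator, spread: float = 0.5) -> np.ndarray:
    """A random non-degenerate 3x18 pose matrix (meters)."""
    return rng.normal(scale=spread, size=(3, 18))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_frame(positions: np.ndarray, **kw) -> PoseFrame:
    return PoseFrame(positions=np.asarray(positions, dtype=float), **kw)
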