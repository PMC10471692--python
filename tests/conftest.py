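import numpy as np
import pytest

from scanbias.detect import DetectorParams
from scanbias.geometry import ScreenGeometry
from scanbias.simulate import SimulatorConfig, simulate_experiment


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def detector_params():
    return DetectorParams()


@pytest.fixture(scope="session")
def small_config(geometry):
    """A reduced session that keeps full-pipeline tests fast."""
    return SimulatorConfig(n_subjects=4, n_scenes=24, geometry=geometry)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config, seed=11)


def make_flat_trace(n_ms=2000, x=400.0, y=300.0, t0=-600,
                    jitter=0.0, rng=None):
    """A constant-position binocular trace (helper for detector tests)."""
    from scanbias.types import GazeTrace
    t = np.arange(t0, t0 + n_ms, dtype=np.int64)
    xs = np.full(n_ms, float(x))
    ys = np.full(n_ms, float(y))
    if jitter and rng is not None:
        xs = xs + rng.normal(0, jitter, n_ms)
        ys = ys + rng.normal(0, jitter, n_ms)
    v = np.ones(n_ms, dtype=bool)
    return GazeTrace(t, xs.copy(), ys.copy(), xs.copy(), ys.copy(),
                     v.copy(), v.copy())
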