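import numpy as np
import pytest

from habtex.raster import Raster


@pytest.fixture
def rng():
    return np.random.default_rng(20130613)


@pytest.fixture
def random_raster(rng):
    return Raster(rng.random((32, 32)) * 255.0)


def simulate_halfnormal_radii(n: int, sigma: float, w: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Detected radii for a point count: uniform-in-disc placement,
    half-normal detection. Independent of the library's generator."""
    out = []
    while len(out) < n:
        r = w * np.sqrt(rng.random(4 * n))
        keep = rng.random(4 * n) < np.exp(-r * r / (2 * sigma * sigma))
        out.extend(r[keep].tolist())
    return np.asarray(out[:n])
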