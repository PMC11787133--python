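import numpy as np
import pytest

from tlsquant import LabelMap, PipelineConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def random_labelmap():
    """Factory for random label maps guaranteed to contain tumor pixels."""

    def make(seed: int, shape=(200, 200), mpp: float = 1.0) -> LabelMap:
        rng = np.random.default_rng(seed)
        pixels = rng.choice(
            [0, 1, 2, 3], size=shape, p=[0.55, 0.25, 0.15, 0.05]
        ).astype(np.uint8)
        if not (pixels == 1).any():  # pragma: no cover - p=0.25 makes this ~impossible
            pixels[0, 0] = 1
        return LabelMap(pixels, mpp=mpp, case_id=f"rand{seed}")

    return make


def brute_force_margin_distance(lmap: LabelMap, point_um) -> float:
    """Independent oracle: minimum Euclidean distance from a physical point
    to any tumor pixel center, by exhaustive scan."""
    rows, cols = np.nonzero(lmap.pixels == 1)
    xs = (cols + 0.5) * lmap.mpp
    ys = (rows + 0.5) * lmap.mpp
    px, py = point_um
    return float(np.sqrt((xs - px) ** 2 + (ys - py) ** 2).min())
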