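import numpy as np
import pytest

from pathomil.core import RGBPatch, SlideLikelihoods


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tile(rng, mean_color, size=64, sd=8.0, slide_id="s", row=0, col=0):
    px = np.clip(rng.normal(mean_color, sd, size=(size, size, 3)), 0, 255).astype(np.uint8)
    return RGBPatch(slide_id=slide_id, grid_row=row, grid_col=col,
                    origin_xy=(col * size, row * size), pixels=px)


@pytest.fixture
def bag_factory():
    def _make(probs, slide_id="bag"):
        probs = np.asarray(probs, dtype=float)
        return SlideLikelihoods(slide_id=slide_id, probabilities=probs,
                                predicted_labels=(probs > 0.5).astype(int))
    return _make


@pytest.fixture
def he_like_patch(rng):
    """A two-dye tile with enough chromatic structure for stain estimation."""
    size = 96
    base = np.array([200.0, 140.0, 185.0])
    px = rng.normal(base, 10.0, size=(size, size, 3))
    # scatter dark hematoxylin-like nuclei
    for _ in range(120):
        r, c = rng.integers(3, size - 3, size=2)
        px[r - 3 : r + 3, c - 3 : c + 3] = (80, 50, 120)
    px = np.clip(px, 0, 255).astype(np.uint8)
    return RGBPatch(slide_id="he", grid_row=0, grid_col=0, origin_xy=(0, 0), pixels=px)
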