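import numpy as np
import pytest

from tumortex import VolumeWithMask, quantize_roi


def volume_from_levels(levels: np.ndarray) -> VolumeWithMask:
    """Wrap an integer level array (0 = background) as a volume whose
    quantization reproduces those exact levels."""
    levels = np.asarray(levels)
    if levels.ndim == 1:
        levels = levels[None, None, :]
    mask = levels > 0
    intensities = np.where(mask, levels.astype(float), -1000.0)
    return VolumeWithMask(intensities, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), mask)


def quantized_from_levels(levels: np.ndarray):
    """QuantizedROI whose levels equal the given integer array exactly.

    Requires the foreground to contain both level 1 and the maximum, so
    equal-width binning is the identity on the given levels.
    """
    levels = np.asarray(levels)
    if levels.ndim == 1:
        levels = levels[None, None, :]
    fg = levels[levels > 0]
    assert fg.min() == 1, "fixture levels must start at 1"
    v = volume_from_levels(levels)
    q = quantize_roi(v, ng=max(2, int(fg.max())))
    np.testing.assert_array_equal(q.levels, levels)
    return q


def random_quantized_roi(rng: np.random.Generator, shape=(6, 6, 6), ng=4):
    """Random small quantized ROI with a random (non-empty) mask."""
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels[~mask] = 0
    # renormalize so max level == ng is not required by the engine; keep as is
    v = volume_from_levels(levels)
    return v, quantize_roi(v, ng=ng), levels


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
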