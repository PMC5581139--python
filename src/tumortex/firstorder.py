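"""First-order intensity statistics (features F1–F14).

Computed over ROI voxel intensities (HU) and, for the histogram-based
entropy and uniformity, over the normalized Ng-bin gray-level histogram
of the quantized ROI.  Moment features use population (1/N)
normalization; kurtosis is non-excess (Gaussian → 3); entropy is in bits
with 0·log 0 ≡ 0.
"""

from __future__ import annotations

import numpy as np

from .volume_io import QuantizedROI, VolumeWithMask

FIRST_ORDER_IDS = [f"F{i}" for i in range(1, 15)]


def _histogram_probs(q: QuantizedROI) -> np.ndarray:
    counts = np.bincount(q.roi_levels, minlength=q.ng + 1)[1:]
    return counts / counts.sum()


def compute_first_order(v: VolumeWithMask, q: QuantizedROI) -> dict[str, float]:
    """Return features F1–F14 for one tumor.

    A constant ROI is degenerate: skewness (F11) and kurtosis (F12) are
    defined as 0 rather than dividing by zero.
    """
    x = v.roi_values
    n = x.size
    mean = x.mean()
    dev = x - mean
    var = float(np.mean(dev**2))
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float(np.mean(dev**3)) / sd**3
        kurt = float(np.mean(dev**4)) / var**2
    else:
        skew = 0.0
        kurt = 0.0
    p = _histogram_probs(q)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())
    return {
        "F1": float((x.astype(np.float64) ** 2).sum()),  # Energy
        "F2": entropy,  # Entropy (histogram, bits)
        "F3": float(x.min()),  # Minimum
        "F4": float(x.max()),  # Maximum
        "F5": float(mean),  # Mean
        "F6": float(np.median(x)),  # Median
        "F7": float(x.max() - x.min()),  # Range
        "F8": float(np.mean(np.abs(dev))),  # Mean deviation
        "F9": float(np.sqrt(np.mean(x.astype(np.float64) ** 2))),  # RMS
        "F10": sd,  # Standard deviation
        "F11": skew,  # Skewness
        "F12": kurt,  # Kurtosis (non-excess)
        "F13": var,  # Variance
        "F14": uniformity,  # Uniformity
    }
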