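"""3D gray-level co-occurrence matrices and Haralick-style features F23–F43.

GLCMs are accumulated over the 13 unique distance-1 offsets of the 3D
26-neighborhood (half of the neighborhood; the other half is covered by
symmetric accumulation, each voxel pair counted in both orders).  Pairs
crossing the mask boundary are skipped.  Each feature is computed per
direction on the normalized symmetric matrix and then averaged,
unweighted, over the non-empty directions, which makes the averaged
features stable under 90° rotations and mirror flips.

Gray levels i, j run 1..Ng.  Logs are base 2 with 0·log 0 ≡ 0.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyROIError
from .volume_io import QuantizedROI

GLCM_IDS = [f"F{i}" for i in range(23, 44)]

#: the 13 unique distance-1 offsets (unique up to sign) of the 26-neighborhood
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def _shifted_views(a: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Views of ``a`` at each voxel and at voxel+offset (overlap region)."""
    sl_a, sl_b = [], []
    for o in offset:
        if o >= 0:
            sl_a.append(slice(None, a.shape[len(sl_a)] - o if o else None))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    return a[tuple(sl_a)], a[tuple(sl_b)]


def build_glcm(q: QuantizedROI, direction: tuple[int, int, int], distance: int = 1):
    """Normalized symmetric GLCM for one offset, or ``None`` if no pair exists.

    Counts each in-mask voxel pair in both orders, then divides by the
    total so the matrix sums to 1.
    """
    off = tuple(int(d) * distance for d in direction)
    if all(o == 0 for o in off):
        raise ValueError("offset must be nonzero")
    lv_a, lv_b = _shifted_views(q.levels, off)
    valid = (lv_a > 0) & (lv_b > 0)
    if not valid.any():
        return None
    i = lv_a[valid].ravel() - 1
    j = lv_b[valid].ravel() - 1
    counts = np.zeros((q.ng, q.ng), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    counts += counts.T  # symmetric accumulation (both pair orders)
    return counts / counts.sum()


def build_glcms(q: QuantizedROI, distance: int = 1) -> list:
    """GLCMs for all 13 directions (``None`` marks empty directions)."""
    return [build_glcm(q, d, distance) for d in DIRECTIONS_3D]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    diff = ii - jj
    absdiff = np.abs(diff)
    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, absdiff.astype(int).ravel(), p.ravel())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    hxy = float(-_xlog2(p).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxy).sum())

    sum_avg = float((ksum * p_sum).sum())
    off_diag = diff != 0
    denom = np.maximum(hx, hy)
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0  # degenerate: constant ROI
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    mu_marginal = mu_x  # symmetric GLCM: mu_x == mu_y
    return {
        "F23": float((ii * jj * p).sum()),  # Autocorrelation
        "F24": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),  # Cluster prominence
        "F25": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),  # Cluster shade
        "F26": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),  # Cluster tendency
        "F27": float((diff**2 * p).sum()),  # Contrast
        "F28": correlation,
        "F29": float(-_xlog2(p_diff).sum()),  # Difference entropy
        "F30": float((absdiff * p).sum()),  # Dissimilarity
        "F31": float((p**2).sum()),  # Energy
        "F32": hxy,  # Entropy
        "F33": float((p / (1.0 + absdiff)).sum()),  # Homogeneity 1
        "F34": float((p / (1.0 + diff**2)).sum()),  # Homogeneity 2
        "F35": imc1,  # Informational measure of correlation 1
        "F36": float((p / (1.0 + diff**2 / ng**2)).sum()),  # IDMN
        "F37": float((p / (1.0 + absdiff / ng)).sum()),  # IDN
        "F38": float((p[off_diag] / diff[off_diag] ** 2).sum()),  # Inverse variance
        "F39": float(p.max()),  # Maximum probability
        "F40": sum_avg,  # Sum average
        "F41": float(-_xlog2(p_sum).sum()),  # Sum entropy
        "F42": float(((ksum - sum_avg) ** 2 * p_sum).sum()),  # Sum variance
        "F43": float(((ii - mu_marginal) ** 2 * p).sum()),  # Variance
    }


def compute_glcm_features(glcms: list) -> dict[str, float]:
    """Average per-direction features over the non-empty directions."""
    mats = [g for g in glcms if g is not None]
    if not mats:
        raise EmptyROIError("no valid voxel pair in any direction")
    acc: dict[str, float] = {k: 0.0 for k in GLCM_IDS}
    for p in mats:
        f = _features_single(p)
        for k in GLCM_IDS:
            acc[k] += f[k]
    return {k: v / len(mats) for k, v in acc.items()}
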