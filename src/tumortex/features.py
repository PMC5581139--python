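"""The 54-feature registry and whole-tumor extraction.

Feature ids F1–F54 are stable column names; :data:`FEATURE_NAMES` maps
them to their conventional labels.  Categories: F1–F14 first-order,
F15–F22 morphology/shape, F23–F43 GLCM texture, F44–F54 run-length
texture.
"""

from __future__ import annotations

import pandas as pd

from .firstorder import compute_first_order
from .glcm import build_glcms, compute_glcm_features
from .glrlm import build_glrlms, compute_glrl_features
from .shape import compute_shape
from .volume_io import VolumeWithMask, quantize_roi

FEATURE_NAMES: dict[str, str] = {
    "F1": "Energy",
    "F2": "Entropy",
    "F3": "Minimum Intensity",
    "F4": "Maximum Intensity",
    "F5": "Mean Intensity",
    "F6": "Median Intensity",
    "F7": "Range",
    "F8": "Mean Deviation",
    "F9": "Root Mean Square",
    "F10": "Standard Deviation",
    "F11": "Skewness",
    "F12": "Kurtosis",
    "F13": "Variance",
    "F14": "Uniformity",
    "F15": "Volume cc",
    "F16": "Surface Area mm^2",
    "F17": "Surface: Volume Ratio",
    "F18": "Compactness 1",
    "F19": "Compactness 2",
    "F20": "Maximum 3D Diameter",
    "F21": "Spherical Disproportion",
    "F22": "Sphericity",
    "F23": "Autocorrelation",
    "F24": "Cluster Prominence",
    "F25": "Cluster Shade",
    "F26": "Cluster Tendency",
    "F27": "Contrast",
    "F28": "Correlation",
    "F29": "Difference Entropy",
    "F30": "Dissimilarity",
    "F31": "Energy (GLCM)",
    "F32": "Entropy (GLCM)",
    "F33": "Homogeneity 1",
    "F34": "Homogeneity 2",
    "F35": "IMC1",
    "F36": "IDMN",
    "F37": "IDN",
    "F38": "Inverse Variance",
    "F39": "Maximum Probability",
    "F40": "Sum Average",
    "F41": "Sum Entropy",
    "F42": "Sum Variance",
    "F43": "Variance (GLCM)",
    "F44": "SRE",
    "F45": "LRE",
    "F46": "GLN",
    "F47": "RLN",
    "F48": "RP",
    "F49": "LGLRE",
    "F50": "HGLRE",
    "F51": "SRLGLE",
    "F52": "SRHGLE",
    "F53": "LRLGLE",
    "F54": "LRHGLE",
}

FEATURE_IDS = list(FEATURE_NAMES)


def extract_features(
    v: VolumeWithMask,
    ng: int = 64,
    surface_estimator: str = "mesh",
    distance: int = 1,
) -> pd.Series:
    """Compute all 54 features for one tumor.

    Parameters
    ----------
    v : VolumeWithMask
        Image + ROI; the mask must be non-empty.
    ng : int
        Number of gray levels for the texture matrices (default 64).
    surface_estimator : {"mesh", "faces"}
        Surface-area estimator for the shape features.
    distance : int
        GLCM offset distance in voxels (default 1).
    """
    v.require_roi()
    q = quantize_roi(v, ng=ng)
    out: dict[str, float] = {}
    out.update(compute_first_order(v, q))
    out.update(compute_shape(v, estimator=surface_estimator))
    out.update(compute_glcm_features(build_glcms(q, distance=distance)))
    out.update(compute_glrl_features(build_glrlms(q), n_voxels=v.n_foreground))
    return pd.Series(out, index=FEATURE_IDS, dtype=float)
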