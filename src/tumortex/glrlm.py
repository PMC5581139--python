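"""Gray-level run-length matrices and features F44–F54.

A run is a maximal streak of voxels with the same gray level along one
of the 13 directions, broken by the mask boundary (a run never jumps
background).  Every foreground voxel belongs to exactly one run per
direction.  Features are computed per direction and averaged over the
non-empty directions, the same convention as the GLCM module.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyROIError
from .glcm import DIRECTIONS_3D
from .volume_io import QuantizedROI

GLRL_IDS = [f"F{i}" for i in range(44, 55)]


def build_glrlm(q: QuantizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix r(i, j) = #maximal runs of level i and length j.

    Returned with shape (Ng, max_run_length); column j (0-based) holds
    runs of length j+1.

    Voxels are grouped into lattice lines of the given direction by their
    line intercept, ordered along the line, and split wherever the line
    id changes, the position jumps (mask gap) or the level changes.
    """
    d = np.asarray(direction, dtype=np.int64)
    coords = np.argwhere(q.mask)
    if coords.size == 0:
        raise EmptyROIError("empty ROI")
    levels = q.levels[q.mask]
    # position along the direction and an integer line id invariant along it:
    # one lattice step along d advances t = v·d by step = d·d, and
    # step·v − t·d is constant on the line.
    t = coords @ d
    step = int(d @ d)
    intercept = coords * step - np.outer(t, d)
    order = np.lexsort((t, intercept[:, 2], intercept[:, 1], intercept[:, 0]))
    t_s = t[order]
    ic_s = intercept[order]
    lv_s = levels[order]
    new_line = np.ones(len(t_s), dtype=bool)
    if len(t_s) > 1:
        same_line = (ic_s[1:] == ic_s[:-1]).all(axis=1)
        contiguous = t_s[1:] == t_s[:-1] + step
        same_level = lv_s[1:] == lv_s[:-1]
        new_line[1:] = ~(same_line & contiguous & same_level)
    starts = np.flatnonzero(new_line)
    run_lengths = np.diff(np.append(starts, len(t_s)))
    run_levels = lv_s[starts]
    r = np.zeros((q.ng, int(run_lengths.max())), dtype=np.float64)
    np.add.at(r, (run_levels - 1, run_lengths - 1), 1.0)
    return r


def build_glrlms(q: QuantizedROI) -> list[np.ndarray]:
    return [build_glrlm(q, d) for d in DIRECTIONS_3D]


def _features_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, max_len = r.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    nr = r.sum()
    return {
        "F44": float((r / j**2).sum() / nr),  # SRE
        "F45": float((r * j**2).sum() / nr),  # LRE
        "F46": float((r.sum(axis=1) ** 2).sum() / nr),  # GLN
        "F47": float((r.sum(axis=0) ** 2).sum() / nr),  # RLN
        "F48": float(nr / n_voxels),  # RP
        "F49": float((r / i**2).sum() / nr),  # LGLRE
        "F50": float((r * i**2).sum() / nr),  # HGLRE
        "F51": float((r / (i**2 * j**2)).sum() / nr),  # SRLGLE
        "F52": float((r * i**2 / j**2).sum() / nr),  # SRHGLE
        "F53": float((r * j**2 / i**2).sum() / nr),  # LRLGLE
        "F54": float((r * i**2 * j**2).sum() / nr),  # LRHGLE
    }


def compute_glrl_features(glrlms: list, n_voxels: int) -> dict[str, float]:
    """Average per-direction run-length features over non-empty directions."""
    mats = [r for r in glrlms if r is not None and r.sum() > 0]
    if not mats:
        raise EmptyROIError("no runs in any direction")
    acc = {k: 0.0 for k in GLRL_IDS}
    for r in mats:
        f = _features_single(r, n_voxels)
        for k in GLRL_IDS:
            acc[k] += f[k]
    return {k: v / len(mats) for k, v in acc.items()}
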