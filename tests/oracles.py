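"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain Python loops over voxels and matrix
cells, deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else 0.0


# ------------------------------------------------------------------ first order


def first_order_oracle(values, hist_probs):
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    xs = sorted(x)
    median = (xs[(n - 1) // 2] + xs[n // 2]) / 2.0
    skew = sum((v - mean) ** 3 for v in x) / n / sd**3 if sd > 0 else 0.0
    kurt = sum((v - mean) ** 4 for v in x) / n / var**2 if sd > 0 else 0.0
    p = list(hist_probs)
    return {
        "F1": sum(v**2 for v in x),
        "F2": -sum(q * _log2(q) for q in p),
        "F3": min(x),
        "F4": max(x),
        "F5": mean,
        "F6": median,
        "F7": max(x) - min(x),
        "F8": sum(abs(v - mean) for v in x) / n,
        "F9": math.sqrt(sum(v**2 for v in x) / n),
        "F10": sd,
        "F11": skew,
        "F12": kurt,
        "F13": var,
        "F14": sum(q**2 for q in p),
    }


# ------------------------------------------------------------------ GLCM


def glcm_oracle(levels: np.ndarray, offset) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix by explicit voxel loops.

    ``levels``: int array with 0 = background, 1..Ng = foreground levels.
    """
    ng = int(levels.max())
    shape = levels.shape
    counts = np.zeros((ng, ng))
    for z, y, x in product(*map(range, shape)):
        a = levels[z, y, x]
        if a == 0:
            continue
        zz, yy, xx = z + offset[0], y + offset[1], x + offset[2]
        if not (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]):
            continue
        b = levels[zz, yy, xx]
        if b == 0:
            continue
        counts[a - 1, b - 1] += 1
        counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else None


def glcm_features_oracle(p: np.ndarray) -> dict:
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    hx = -sum(q * _log2(q) for q in px)
    hy = -sum(q * _log2(q) for q in py)
    hxy = -sum(p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(ng))
    hxy1 = -sum(
        p[i, j] * _log2(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    sum_avg = sum(k * v for k, v in p_sum.items())
    f = {}
    f["F23"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    for key, power in (("F24", 4), ("F25", 3), ("F26", 2)):
        f[key] = sum(
            (i + 1 + j + 1 - mu_x - mu_y) ** power * p[i, j]
            for i in range(ng)
            for j in range(ng)
        )
    f["F27"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if sd_x > 0 and sd_y > 0:
        f["F28"] = (f["F23"] - mu_x * mu_y) / (sd_x * sd_y)
    else:
        f["F28"] = 0.0
    f["F29"] = -sum(v * _log2(v) for v in p_diff.values())
    f["F30"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    f["F31"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["F32"] = hxy
    f["F33"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["F34"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    denom = max(hx, hy)
    f["F35"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["F36"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    f["F37"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    f["F38"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["F39"] = max(p[i, j] for i in range(ng) for j in range(ng))
    f["F40"] = sum_avg
    f["F41"] = -sum(v * _log2(v) for v in p_sum.values())
    f["F42"] = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    f["F43"] = sum(
        (i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    return f


def glcm_all_directions_oracle(levels: np.ndarray) -> dict:
    feats = []
    for d in DIRECTIONS:
        p = glcm_oracle(levels, d)
        if p is not None:
            feats.append(glcm_features_oracle(p))
    keys = feats[0].keys()
    return {k: sum(f[k] for f in feats) / len(feats) for k in keys}


# ------------------------------------------------------------------ GLRLM


def glrlm_oracle(levels: np.ndarray, direction) -> dict:
    """Run counts {(level, length): n} by walking each run from its start."""
    shape = levels.shape
    d = direction
    runs: dict[tuple[int, int], int] = {}

    def inside(v):
        return all(0 <= v[k] < shape[k] for k in range(3))

    for z, y, x in product(*map(range, shape)):
        lv = levels[z, y, x]
        if lv == 0:
            continue
        prev = (z - d[0], y - d[1], x - d[2])
        if inside(prev) and levels[prev] == lv:
            continue  # not a run start
        length = 1
        cur = (z + d[0], y + d[1], x + d[2])
        while inside(cur) and levels[cur] == lv:
            length += 1
            cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
        runs[(int(lv), length)] = runs.get((int(lv), length), 0) + 1
    return runs


def glrl_features_oracle(runs: dict, n_voxels: int) -> dict:
    nr = sum(runs.values())
    def s(fn):
        return sum(fn(i, j) * c for (i, j), c in runs.items()) / nr
    return {
        "F44": s(lambda i, j: 1 / j**2),
        "F45": s(lambda i, j: j**2),
        "F46": sum(
            (sum(c for (i2, _), c in runs.items() if i2 == i)) ** 2
            for i in {i for i, _ in runs}
        ) / nr,
        "F47": sum(
            (sum(c for (_, j2), c in runs.items() if j2 == j)) ** 2
            for j in {j for _, j in runs}
        ) / nr,
        "F48": nr / n_voxels,
        "F49": s(lambda i, j: 1 / i**2),
        "F50": s(lambda i, j: i**2),
        "F51": s(lambda i, j: 1 / (i**2 * j**2)),
        "F52": s(lambda i, j: i**2 / j**2),
        "F53": s(lambda i, j: j**2 / i**2),
        "F54": s(lambda i, j: i**2 * j**2),
    }


def glrl_all_directions_oracle(levels: np.ndarray, n_voxels: int) -> dict:
    feats = [
        glrl_features_oracle(glrlm_oracle(levels, d), n_voxels) for d in DIRECTIONS
    ]
    keys = feats[0].keys()
    return {k: sum(f[k] for f in feats) / len(feats) for k in keys}


# ------------------------------------------------------------------ misc


def max_diameter_oracle(mask: np.ndarray, spacing) -> float:
    pts = [
        (z * spacing[0], y * spacing[1], x * spacing[2])
        for z, y, x in zip(*np.nonzero(mask))
    ]
    best = 0.0
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            d = math.dist(pts[a], pts[b])
            best = max(best, d)
    return best


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))
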