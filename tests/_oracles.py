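"""Independent brute-force reference implementations used only by tests.

Everything here is written as straight loops over definitions, deliberately
sharing no code with the package internals it checks.
"""

from itertools import combinations
from math import log2
from typing import Dict, List, Sequence, Tuple

import numpy as np

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_window_oracle(levels: np.ndarray, cy: int, cx: int, window: int,
                       n_levels: int) -> np.ndarray:
    """Normalized symmetric GLCM of the window at (cy, cx), clipped at borders."""
    r = window // 2
    h, w = levels.shape
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    counts = np.zeros((n_levels, n_levels))
    for y in range(y0, y1):
        for x in range(x0, x1):
            for dy, dx in OFFSETS:
                yy, xx = y + dy, x + dx
                if y0 <= yy < y1 and x0 <= xx < x1:
                    a, b = levels[y, x], levels[yy, xx]
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    return counts / total


def haralick_oracle(P: np.ndarray) -> Dict[str, float]:
    """The 13 co-occurrence statistics evaluated term by term."""
    L = P.shape[0]
    ent = -sum(P[i, j] * log2(P[i, j])
               for i in range(L) for j in range(L) if P[i, j] > 0)
    energy = float((P ** 2).sum())
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = sum(i * px[i] for i in range(L))
    my = sum(j * py[j] for j in range(L))
    vx = sum((i - mx) ** 2 * px[i] for i in range(L))
    vy = sum((j - my) ** 2 * py[j] for j in range(L))
    if vx > 0 and vy > 0:
        corr = (sum(i * j * P[i, j] for i in range(L) for j in range(L))
                - mx * my) / np.sqrt(vx * vy)
    else:
        corr = 0.0

    hx = -sum(px[i] * log2(px[i]) for i in range(L) if px[i] > 0)
    hy = -sum(py[j] * log2(py[j]) for j in range(L) if py[j] > 0)
    hxy1 = -sum(P[i, j] * log2(px[i] * py[j])
                for i in range(L) for j in range(L)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0

    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    sa = sum(k * psum[k] for k in range(2 * L - 1))
    sv = sum((k - sa) ** 2 * psum[k] for k in range(2 * L - 1))
    se = -sum(psum[k] * log2(psum[k]) for k in range(2 * L - 1) if psum[k] > 0)
    da = sum(k * pdiff[k] for k in range(L))
    dv = sum((k - da) ** 2 * pdiff[k] for k in range(L))
    de = -sum(pdiff[k] * log2(pdiff[k]) for k in range(L) if pdiff[k] > 0)

    return {"entropy": ent, "energy": energy, "inertia": contrast,
            "inverse_difference_moment": idm, "correlation": corr,
            "info_corr1": imc1, "sum_average": sa, "sum_variance": sv,
            "sum_entropy": se, "difference_average": da,
            "difference_variance": dv, "difference_entropy": de,
            "contrast": contrast}


def quantize_oracle(values: np.ndarray, n_levels: int, lo: float,
                    hi: float) -> np.ndarray:
    out = np.empty(values.shape, dtype=int)
    width = (hi - lo) / n_levels
    it = np.nditer(values, flags=["multi_index"])
    for v in it:
        if hi <= lo:
            lev = 0
        else:
            lev = int((float(v) - lo) // width)
            lev = min(max(lev, 0), n_levels - 1)
        out[it.multi_index] = lev
    return out


def auc_pairs_oracle(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC by counting all positive-negative score pairs (ties worth 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ranksum_exact_oracle(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    pooled = sorted(list(a) + list(b))
    n, na = len(pooled), len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by assumption
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    mean_u = na * (n - na) / 2
    count = 0
    total = 0
    for comb in combinations(range(1, n + 1), na):
        u = sum(comb) - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def collage_window_oracle(gx: np.ndarray, gy: np.ndarray, cy: int, cx: int,
                          window: int, n_bins: int) -> float:
    """Gradient-orientation entropy at one voxel via explicit eigen-analysis."""
    r = window // 2
    h, w = gx.shape

    def dominant_angle(y: int, x: int) -> float:
        y0, y1 = max(0, y - r), min(h, y + r + 1)
        x0, x1 = max(0, x - r), min(w, x + r + 1)
        g = np.stack([gx[y0:y1, x0:x1].ravel(), gy[y0:y1, x0:x1].ravel()])
        scatter = g @ g.T
        vals, vecs = np.linalg.eigh(scatter)
        v = vecs[:, np.argmax(vals)]
        return float(np.mod(np.arctan2(v[1], v[0]), np.pi))

    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    energy = float((gx[y0:y1, x0:x1] ** 2).sum()
                   + (gy[y0:y1, x0:x1] ** 2).sum())
    bins: List[int] = []
    for y in range(y0, y1):
        for x in range(x0, x1):
            theta = dominant_angle(y, x)
            bins.append(min(int(theta / (np.pi / n_bins)), n_bins - 1))
    if energy == 0:
        return 0.0
    counts = np.bincount(bins, minlength=n_bins)
    p = counts / counts.sum()
    return float(-sum(q * log2(q) for q in p if q > 0))


def moments_oracle(values: Sequence[float]) -> Tuple[float, float, float, float]:
    v = list(map(float, values))
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    if n < 3 or var == 0:
        return mean, var, 0.0, 0.0
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    return mean, var, m3 / var ** 1.5, m4 / var ** 2 - 3.0


def mi_oracle(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information in bits from the empirical joint."""
    n = len(x)
    states_x = sorted(set(x))
    states_y = sorted(set(y))
    mi = 0.0
    for sx in states_x:
        for sy in states_y:
            pxy = sum(1 for a, b in zip(x, y) if a == sx and b == sy) / n
            if pxy == 0:
                continue
            px = sum(1 for a in x if a == sx) / n
            py = sum(1 for b in y if b == sy) / n
            mi += pxy * log2(pxy / (px * py))
    return mi
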