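"""Per-voxel 2D texture descriptors: windowed Haralick, Gabor bank, CoLlAGe.

All operators act on a single axial slice. Windows are centered on ROI voxels,
clipped at image borders, and include window voxels that fall outside the ROI
(the ROI gates only which centers are evaluated). Entropies are in bits.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

#: the four 2D co-occurrence offsets (row, col), pooled into one matrix
GLCM_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

HARALICK_NAMES: Tuple[str, ...] = (
    "entropy", "energy", "inertia", "inverse_difference_moment", "correlation",
    "info_corr1", "sum_average", "sum_variance", "sum_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "contrast",
)

GABOR_ORIENTATIONS_DEG: Tuple[float, ...] = (0.0, 36.0, 72.0, 108.0, 144.0)
GABOR_NAMES: Tuple[str, ...] = tuple(
    f"orient{int(round(t)):03d}" for t in GABOR_ORIENTATIONS_DEG)

DEFAULT_N_LEVELS = 16
HARALICK_WINDOWS: Tuple[int, ...] = (3, 5, 7)
COLLAGE_WINDOW = 5
COLLAGE_BINS = 8

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Quantization and GLCM


def quantize(values: np.ndarray, n_levels: int,
             value_range: Tuple[float, float]) -> np.ndarray:
    """Equal-width quantization of ``values`` over a fixed range.

    The range is meant to be computed once per lesion-slice ROI so that
    neighbouring windows share a gray-level scale. Values at the range maximum
    map to the top level; values outside the range are clipped into the end
    bins. A constant range maps everything to level 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lo, hi = float(value_range[0]), float(value_range[1])
    v = np.asarray(values, dtype=np.float64)
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.int64)
    t = (v - lo) / (hi - lo) * n_levels
    return np.clip(np.floor(t), 0, n_levels - 1).astype(np.int64)


def compute_glcm(level_patch: np.ndarray,
                 offsets: Sequence[Tuple[int, int]] = GLCM_OFFSETS,
                 n_levels: int | None = None,
                 symmetric: bool = True) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of one 2D level patch.

    Co-occurring level pairs are accumulated over the given offsets, pooled
    into a single matrix (symmetric counting by default), then normalized to
    sum to one. Levels < 0 are treated as invalid (outside the image).
    """
    patch = np.asarray(level_patch)
    if patch.ndim != 2:
        raise ValueError("level patch must be 2D")
    if n_levels is None:
        n_levels = int(patch.max()) + 1
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    h, w = patch.shape
    for dy, dx in offsets:
        ra, rb = slice(0, h - dy), slice(dy, h)
        if dx >= 0:
            ca, cb = slice(0, w - dx), slice(dx, w)
        else:
            ca, cb = slice(-dx, w), slice(0, w + dx)
        a = patch[ra, ca].ravel()
        b = patch[rb, cb].ravel()
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
        np.add.at(counts, (a, b), 1.0)
        if symmetric:
            np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("patch has no valid co-occurrence pairs")
    return counts / total


@lru_cache(maxsize=8)
def _sum_diff_projectors(n_levels: int) -> Tuple[np.ndarray, np.ndarray]:
    """0/1 matrices projecting a flattened GLCM onto p_{x+y} and p_{|x-y|}."""
    i, j = np.meshgrid(np.arange(n_levels), np.arange(n_levels), indexing="ij")
    s_idx = (i + j).ravel()
    d_idx = np.abs(i - j).ravel()
    S = np.zeros((n_levels * n_levels, 2 * n_levels - 1))
    D = np.zeros((n_levels * n_levels, n_levels))
    S[np.arange(s_idx.size), s_idx] = 1.0
    D[np.arange(d_idx.size), d_idx] = 1.0
    return S, D


def _plog2p(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_stats_batch(glcms: np.ndarray) -> np.ndarray:
    """The 13 co-occurrence statistics for a stack of normalized GLCMs.

    Parameters
    ----------
    glcms : array of shape (n, L, L), each slice summing to one.

    Returns
    -------
    array of shape (n, 13), columns ordered as :data:`HARALICK_NAMES`.
    """
    P = np.asarray(glcms, dtype=np.float64)
    if P.ndim == 2:
        P = P[None]
    n, L, _ = P.shape
    lev = np.arange(L, dtype=np.float64)
    i = lev[None, :, None]
    j = lev[None, None, :]

    px = P.sum(axis=2)                       # (n, L)
    py = P.sum(axis=1)
    mu_x = (px * lev).sum(axis=1)
    mu_y = (py * lev).sum(axis=1)
    var_x = (px * (lev[None, :] - mu_x[:, None]) ** 2).sum(axis=1)
    var_y = (py * (lev[None, :] - mu_y[:, None]) ** 2).sum(axis=1)

    entropy = -_plog2p(P).sum(axis=(1, 2))
    energy = (P ** 2).sum(axis=(1, 2))
    contrast = (P * (i - j) ** 2).sum(axis=(1, 2))
    inertia = contrast.copy()                # classical synonym; pruned downstream
    idm = (P / (1.0 + (i - j) ** 2)).sum(axis=(1, 2))

    sxy = np.sqrt(var_x * var_y)
    cov = (P * i * j).sum(axis=(1, 2)) - mu_x * mu_y
    correlation = np.where(sxy > _EPS, cov / np.where(sxy > _EPS, sxy, 1.0), 0.0)

    hx = -_plog2p(px).sum(axis=1)
    hy = -_plog2p(py).sum(axis=1)
    pxy_prod = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_prod = np.where(pxy_prod > 0, np.log2(np.where(pxy_prod > 0, pxy_prod, 1.0)), 0.0)
    hxy1 = -(P * log_prod).sum(axis=(1, 2))
    hmax = np.maximum(hx, hy)
    info_corr1 = np.where(hmax > _EPS, (entropy - hxy1) / np.where(hmax > _EPS, hmax, 1.0), 0.0)

    S, D = _sum_diff_projectors(L)
    flat = P.reshape(n, L * L)
    psum = flat @ S                          # (n, 2L-1), k = i + j
    pdiff = flat @ D                         # (n, L),   k = |i - j|
    ks = np.arange(2 * L - 1, dtype=np.float64)
    kd = np.arange(L, dtype=np.float64)
    sum_average = (psum * ks).sum(axis=1)
    sum_variance = (psum * (ks[None, :] - sum_average[:, None]) ** 2).sum(axis=1)
    sum_entropy = -_plog2p(psum).sum(axis=1)
    diff_average = (pdiff * kd).sum(axis=1)
    diff_variance = (pdiff * (kd[None, :] - diff_average[:, None]) ** 2).sum(axis=1)
    diff_entropy = -_plog2p(pdiff).sum(axis=1)

    return np.stack([entropy, energy, inertia, idm, correlation, info_corr1,
                     sum_average, sum_variance, sum_entropy, diff_average,
                     diff_variance, diff_entropy, contrast], axis=1)


def haralick_stats(glcm: np.ndarray) -> Dict[str, float]:
    """The 13 statistics of a single normalized GLCM, by name."""
    P = np.asarray(glcm, dtype=np.float64)
    if abs(P.sum() - 1.0) > 1e-9 or (P < 0).any():
        raise ValueError("haralick_stats expects a normalized GLCM")
    row = haralick_stats_batch(P[None])[0]
    return dict(zip(HARALICK_NAMES, (float(v) for v in row)))


# ---------------------------------------------------------------------------
# Windowed Haralick maps


def haralick_maps(slice2d: np.ndarray, roi_slice: np.ndarray, window: int,
                  n_levels: int = DEFAULT_N_LEVELS) -> Dict[str, np.ndarray]:
    """13 per-voxel Haralick maps from the GLCM of the window at each ROI voxel.

    Quantization range is fixed from the slice's ROI intensities; windows are
    clipped at image borders and include non-ROI voxels. Returns full-slice
    maps with NaN outside the ROI.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    slice2d = np.asarray(slice2d, dtype=np.float64)
    roi = np.asarray(roi_slice).astype(bool)
    if slice2d.shape != roi.shape:
        raise ValueError("slice and ROI shapes differ")
    empty = {name: np.full(slice2d.shape, np.nan) for name in HARALICK_NAMES}
    if not roi.any():
        return empty

    roi_vals = slice2d[roi]
    levels = quantize(slice2d, n_levels, (roi_vals.min(), roi_vals.max()))
    r = window // 2
    pad = np.pad(levels, r, constant_values=-1)
    patches = sliding_window_view(pad, (window, window))[roi]   # (n, w, w)
    n = patches.shape[0]
    L = n_levels

    counts = np.zeros((n, L * L), dtype=np.float64)
    rows = np.broadcast_to(np.arange(n)[:, None], (n, window * window))
    for dy, dx in GLCM_OFFSETS:
        ra, rb = slice(0, window - dy), slice(dy, window)
        if dx >= 0:
            ca, cb = slice(0, window - dx), slice(dx, window)
        else:
            ca, cb = slice(-dx, window), slice(0, window + dx)
        a = patches[:, ra, ca].reshape(n, -1)
        b = patches[:, rb, cb].reshape(n, -1)
        ok = (a >= 0) & (b >= 0)
        rr = np.broadcast_to(np.arange(n)[:, None], a.shape)
        np.add.at(counts, (rr[ok], (a * L + b)[ok]), 1.0)
        np.add.at(counts, (rr[ok], (b * L + a)[ok]), 1.0)

    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("window with no valid co-occurrence pairs")
    stats = haralick_stats_batch((counts / totals[:, None]).reshape(n, L, L))

    maps = {}
    for k, name in enumerate(HARALICK_NAMES):
        m = np.full(slice2d.shape, np.nan)
        m[roi] = stats[:, k]
        maps[name] = m
    return maps


# ---------------------------------------------------------------------------
# Gabor bank


def gabor_kernel(orientation_deg: float, wavelength: float = 4.0,
                 sigma: float | None = None) -> np.ndarray:
    """Zero-DC real Gabor kernel (cosine carrier under a Gaussian envelope).

    Orientation 0 varies along columns, i.e. responds to vertical stripes.
    """
    if sigma is None:
        sigma = wavelength / 2.0
    half = int(np.ceil(3.0 * sigma))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    row, col = np.meshgrid(ax, ax, indexing="ij")
    theta = np.deg2rad(orientation_deg)
    u = np.cos(theta) * col + np.sin(theta) * row
    envelope = np.exp(-(row ** 2 + col ** 2) / (2.0 * sigma ** 2))
    kern = envelope * np.cos(2.0 * np.pi * u / wavelength)
    return kern - kern.mean()    # zero DC: constant images give zero response


def default_gabor_bank(wavelength: float = 4.0) -> List[np.ndarray]:
    return [gabor_kernel(t, wavelength) for t in GABOR_ORIENTATIONS_DEG]


def gabor_maps(slice2d: np.ndarray, roi_slice: np.ndarray,
               bank: Sequence[np.ndarray] | None = None) -> Dict[str, np.ndarray]:
    """Per-voxel response magnitude for each filter in the bank, on ROI voxels."""
    slice2d = np.asarray(slice2d, dtype=np.float64)
    roi = np.asarray(roi_slice).astype(bool)
    if bank is None:
        bank = default_gabor_bank()
    maps: Dict[str, np.ndarray] = {}
    for name, kern in zip(GABOR_NAMES, bank):
        if kern.shape[0] > slice2d.shape[0] or kern.shape[1] > slice2d.shape[1]:
            raise ValueError(
                f"Gabor kernel {kern.shape} larger than slice {slice2d.shape}")
        resp = np.abs(ndimage.convolve(slice2d, kern, mode="reflect"))
        m = np.full(slice2d.shape, np.nan)
        m[roi] = resp[roi]
        maps[name] = m
    return maps


# ---------------------------------------------------------------------------
# CoLlAGe


def _box_sum(img: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window sum with windows clipped at the image borders.

    Works on (H, W) or (H, W, C) arrays; the window slides over the first two
    axes.
    """
    r = window // 2
    H, W = img.shape[:2]
    ii = img.cumsum(axis=0).cumsum(axis=1)
    pad_width = ((1, 0), (1, 0)) + ((0, 0),) * (img.ndim - 2)
    ii = np.pad(ii, pad_width)
    y = np.arange(H)
    x = np.arange(W)
    y0 = np.clip(y - r, 0, H)
    y1 = np.clip(y + r + 1, 0, H)
    x0 = np.clip(x - r, 0, W)
    x1 = np.clip(x + r + 1, 0, W)
    A = ii[np.ix_(y1, x1)]
    B = ii[np.ix_(y0, x1)]
    C = ii[np.ix_(y1, x0)]
    Dm = ii[np.ix_(y0, x0)]
    return A - B - C + Dm


def collage_map(slice2d: np.ndarray, roi_slice: np.ndarray,
                window: int = COLLAGE_WINDOW,
                n_bins: int = COLLAGE_BINS) -> np.ndarray:
    """Gradient-orientation entropy (CoLlAGe) at each ROI voxel.

    Per voxel: Sobel gradients; dominant orientation = first principal
    direction of the window's gradient scatter matrix; orientations quantized
    into ``n_bins`` over [0, pi); value = Shannon entropy (bits) of the binned
    orientation distribution inside the window. Windows whose gradients are
    all zero get entropy 0.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    slice2d = np.asarray(slice2d, dtype=np.float64)
    roi = np.asarray(roi_slice).astype(bool)
    out = np.full(slice2d.shape, np.nan)
    if not roi.any():
        return out

    gx = ndimage.sobel(slice2d, axis=0, mode="reflect")
    gy = ndimage.sobel(slice2d, axis=1, mode="reflect")

    sxx = _box_sum(gx * gx, window)
    syy = _box_sum(gy * gy, window)
    sxy = _box_sum(gx * gy, window)
    # angle of the leading eigenvector of [[sxx, sxy], [sxy, syy]], mod pi
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    theta = np.mod(theta, np.pi)
    bins = np.clip(np.floor(theta / (np.pi / n_bins)), 0, n_bins - 1).astype(int)

    onehot = np.zeros(slice2d.shape + (n_bins,))
    np.put_along_axis(onehot, bins[:, :, None], 1.0, axis=2)
    bin_counts = _box_sum(onehot, window)
    totals = bin_counts.sum(axis=2)
    p = bin_counts / np.maximum(totals, 1.0)[:, :, None]
    entropy = -_plog2p(p).sum(axis=2)

    # degenerate windows: no gradient energy anywhere in the window
    grad_energy = _box_sum(gx * gx + gy * gy, window)
    entropy = np.where(grad_energy <= _EPS, 0.0, entropy)

    out[roi] = entropy[roi]
    return out
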