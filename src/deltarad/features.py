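"""Lesion-level radiomic feature vectors and delta features.

Per sequence a lesion yields 252 named features:

* 18 first-order statistics computed per axial slice, each summarized by 4
  distribution moments across slices (72 features);
* 45 per-voxel descriptor maps (13 Haralick statistics x 3 window sizes,
  5 Gabor orientations, 1 CoLlAGe), each pooled over all lesion voxels of all
  slices and summarized by the same 4 moments (180 features).

Delta features are entrywise follow-up minus baseline. Names follow
``<aggstat>_<family>_<descriptor>[_w<window>]``.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .images import ImageVolume, RoiMask
from .texture import (COLLAGE_BINS, COLLAGE_WINDOW, DEFAULT_N_LEVELS,
                      GABOR_NAMES, HARALICK_NAMES, HARALICK_WINDOWS,
                      collage_map, default_gabor_bank, gabor_maps,
                      haralick_maps)

AGG_STATS: Tuple[str, ...] = ("mean", "variance", "skewness", "kurtosis")

FIRST_ORDER_NAMES: Tuple[str, ...] = (
    "mean", "median", "std", "range", "min", "max", "p10", "p25", "p75",
    "p90", "iqr", "skewness", "kurtosis", "energy", "rms", "mad",
    "hist_entropy", "uniformity",
)

#: margin (voxels) of context kept around the lesion so that every texture
#: window / kernel centered on a ROI voxel sees the same neighbourhood it
#: would in the uncropped slice
CONTEXT_MARGIN = 8

FeatureVector = Dict[str, float]


def feature_names() -> List[str]:
    """The canonical ordered 252-entry name list (one sequence)."""
    names: List[str] = []
    for desc in FIRST_ORDER_NAMES:
        for agg in AGG_STATS:
            names.append(f"{agg}_firstorder_{desc}")
    for w in HARALICK_WINDOWS:
        for desc in HARALICK_NAMES:
            for agg in AGG_STATS:
                names.append(f"{agg}_haralick_{desc}_w{w}")
    for desc in GABOR_NAMES:
        for agg in AGG_STATS:
            names.append(f"{agg}_gabor_{desc}")
    for agg in AGG_STATS:
        names.append(f"{agg}_collage")
    return names


def _moments(values: np.ndarray) -> Tuple[float, float, float, float]:
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    mean = float(v.mean())
    var = float(v.var())          # population variance
    if n < 3 or var <= 0:
        return mean, var, 0.0, 0.0
    c = v - mean
    m2 = float((c ** 2).mean())
    skew = float((c ** 3).mean() / m2 ** 1.5)
    kurt = float((c ** 4).mean() / m2 ** 2 - 3.0)   # excess kurtosis
    return mean, var, skew, kurt


def aggregate_lesion(values: Sequence[float] | np.ndarray
                     ) -> Tuple[float, float, float, float]:
    """Lesion-level distribution moments (mean, variance, skewness, kurtosis).

    Variance is population-style; skewness/kurtosis of fewer than 3 values or
    zero-variance data are defined as 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty value set")
    return _moments(v)


def first_order_slice(slice2d: np.ndarray, roi_slice: np.ndarray,
                      hist_bins: int = 32) -> Dict[str, float]:
    """The 18 first-order statistics of the ROI intensities of one slice."""
    roi = np.asarray(roi_slice).astype(bool)
    if not roi.any():
        raise ValueError("empty ROI slice")
    v = np.asarray(slice2d, dtype=np.float64)[roi]
    mean, var, skew, kurt = _moments(v)
    p10, p25, med, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        hist, _ = np.histogram(v, bins=hist_bins, range=(vmin, vmax))
        p = hist / hist.sum()
        nz = p > 0
        hist_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
        uniformity = float((p ** 2).sum())
    else:
        hist_entropy, uniformity = 0.0, 1.0
    return {
        "mean": mean,
        "median": float(med),
        "std": float(np.sqrt(var)),
        "range": vmax - vmin,
        "min": vmin,
        "max": vmax,
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((v ** 2).sum()),
        "rms": float(np.sqrt((v ** 2).mean())),
        "mad": float(np.abs(v - mean).mean()),
        "hist_entropy": hist_entropy,
        "uniformity": uniformity,
    }


def _lesion_crop(mask: RoiMask, shape: Tuple[int, int, int]
                 ) -> Tuple[slice, slice]:
    """In-plane bounding box of the lesion plus texture context margin."""
    any_xy = mask.array.any(axis=2)
    xs, ys = np.nonzero(any_xy)
    x0 = max(0, xs.min() - CONTEXT_MARGIN)
    x1 = min(shape[0], xs.max() + 1 + CONTEXT_MARGIN)
    y0 = max(0, ys.min() - CONTEXT_MARGIN)
    y1 = min(shape[1], ys.max() + 1 + CONTEXT_MARGIN)
    return slice(x0, x1), slice(y0, y1)


def extract_features(volume: ImageVolume, mask: RoiMask,
                     n_levels: int = DEFAULT_N_LEVELS,
                     haralick_windows: Sequence[int] = HARALICK_WINDOWS,
                     gabor_wavelength: float = 4.0,
                     collage_window: int = COLLAGE_WINDOW,
                     collage_bins: int = COLLAGE_BINS) -> FeatureVector:
    """Extract the 252-entry feature vector of one lesion on one sequence.

    First-order statistics are computed per slice and summarized across
    slices; texture map values are pooled over all lesion voxels of all
    slices before summarization.
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    slice_idx = mask.slice_indices()
    if slice_idx.size == 0:
        raise ValueError("empty lesion mask")

    sx, sy = _lesion_crop(mask, volume.shape)
    bank = default_gabor_bank(gabor_wavelength)

    fo_rows: List[List[float]] = []
    map_pools: Dict[str, List[np.ndarray]] = {}
    for w in haralick_windows:
        for desc in HARALICK_NAMES:
            map_pools[f"haralick_{desc}_w{w}"] = []
    for desc in GABOR_NAMES:
        map_pools[f"gabor_{desc}"] = []
    map_pools["collage"] = []

    for k in slice_idx:
        sl = volume.array[sx, sy, k]
        roi = mask.array[sx, sy, k]
        fo = first_order_slice(sl, roi)
        fo_rows.append([fo[name] for name in FIRST_ORDER_NAMES])

        for w in haralick_windows:
            hmaps = haralick_maps(sl, roi, w, n_levels=n_levels)
            for desc in HARALICK_NAMES:
                map_pools[f"haralick_{desc}_w{w}"].append(hmaps[desc][roi])
        gmaps = gabor_maps(sl, roi, bank)
        for desc in GABOR_NAMES:
            map_pools[f"gabor_{desc}"].append(gmaps[desc][roi])
        cmap = collage_map(sl, roi, window=collage_window, n_bins=collage_bins)
        map_pools["collage"].append(cmap[roi])

    features: FeatureVector = {}
    fo_arr = np.asarray(fo_rows)            # (n_slices, 18)
    for d, desc in enumerate(FIRST_ORDER_NAMES):
        for agg, val in zip(AGG_STATS, aggregate_lesion(fo_arr[:, d])):
            features[f"{agg}_firstorder_{desc}"] = val
    for key, chunks in map_pools.items():
        pooled = np.concatenate(chunks)
        for agg, val in zip(AGG_STATS, aggregate_lesion(pooled)):
            features[f"{agg}_{key}"] = val

    ordered = {name: features[name] for name in feature_names()}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad[:5]}")
    return ordered


def delta_features(fv_followup: FeatureVector,
                   fv_baseline: FeatureVector) -> FeatureVector:
    """Entrywise follow-up minus baseline; name sets must match."""
    if set(fv_followup) != set(fv_baseline):
        raise ValueError("feature name sets differ between timepoints")
    return {name: fv_followup[name] - fv_baseline[name] for name in fv_followup}
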