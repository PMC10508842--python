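"""Landmark-based T2W intensity standardization and mask resampling.

T2W intensities have no tissue-specific meaning across scans; the classic fix
maps each scan's histogram landmarks (deciles with robust min/max anchors)
onto a template learned from a reference set, by piecewise-linear
interpolation. ADC maps are quantitative and must never pass through this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

from .images import ImageVolume, RoiMask

#: deciles 10..90 with 1st/99th percentile anchors (robust min/max)
DEFAULT_PERCENTILES: Tuple[float, ...] = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                                          60.0, 70.0, 80.0, 90.0, 99.0)


@dataclass
class StandardizationTemplate:
    """Histogram landmarks on the standard intensity scale."""

    landmark_percentiles: Tuple[float, ...]
    landmark_values: Tuple[float, ...]

    def __post_init__(self) -> None:
        self.landmark_percentiles = tuple(float(p) for p in self.landmark_percentiles)
        self.landmark_values = tuple(float(v) for v in self.landmark_values)
        if len(self.landmark_percentiles) != len(self.landmark_values):
            raise ValueError("percentiles and values must have equal length")
        pv = np.asarray(self.landmark_percentiles)
        if np.any(np.diff(pv) <= 0):
            raise ValueError("landmark percentiles must be strictly increasing")
        vv = np.asarray(self.landmark_values)
        if np.any(np.diff(vv) <= 0):
            raise ValueError("landmark values must be strictly increasing")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"landmark_percentiles": list(self.landmark_percentiles),
                       "landmark_values": list(self.landmark_values)}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationTemplate":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["landmark_percentiles"]), tuple(d["landmark_values"]))


def _region_values(volume: ImageVolume, mask: RoiMask | None) -> np.ndarray:
    if mask is not None:
        vals = volume.array[mask.array]
    else:
        # default region: the nonzero "body" voxels
        arr = volume.array
        vals = arr[arr != 0]
        if vals.size == 0:
            vals = arr.ravel()
    return vals


def volume_landmarks(volume: ImageVolume, percentiles: Sequence[float],
                     mask: RoiMask | None = None) -> np.ndarray:
    vals = _region_values(volume, mask)
    if vals.size == 0:
        raise ValueError("no voxels in standardization region")
    if vals.max() == vals.min():
        raise ValueError("constant-intensity volume has degenerate landmarks")
    return np.percentile(vals, percentiles)


def learn_template(volumes: Sequence[ImageVolume],
                   masks: Sequence[RoiMask] | None = None,
                   percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                   ) -> StandardizationTemplate:
    """Average per-percentile landmarks across reference volumes."""
    if len(volumes) == 0:
        raise ValueError("need at least one volume to learn a template")
    pv = np.asarray(percentiles, dtype=float)
    if np.any(pv <= 0) or np.any(pv >= 100) or np.any(np.diff(pv) <= 0):
        raise ValueError("percentiles must be strictly increasing in (0, 100)")
    marks = []
    for i, vol in enumerate(volumes):
        mask = masks[i] if masks is not None else None
        marks.append(volume_landmarks(vol, pv, mask))
    values = np.mean(marks, axis=0)
    return StandardizationTemplate(tuple(pv), tuple(values))


def piecewise_linear_map(values: np.ndarray, src_landmarks: np.ndarray,
                         dst_landmarks: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear map with linear extrapolation beyond anchors."""
    src = np.asarray(src_landmarks, dtype=float)
    dst = np.asarray(dst_landmarks, dtype=float)
    out = np.interp(values, src, dst)
    # np.interp clamps outside the anchors; continue the outer segments instead
    lo, hi = src[0], src[-1]
    slope_lo = (dst[1] - dst[0]) / (src[1] - src[0])
    slope_hi = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    below = values < lo
    above = values > hi
    out = np.where(below, dst[0] + (values - lo) * slope_lo, out)
    out = np.where(above, dst[-1] + (values - hi) * slope_hi, out)
    return out


def standardize(volume: ImageVolume, template: StandardizationTemplate,
                mask: RoiMask | None = None) -> ImageVolume:
    """Map a volume onto the template's standard intensity scale."""
    if volume.sequence == "ADC":
        raise ValueError("ADC maps are quantitative and are never standardized")
    src = volume_landmarks(volume, template.landmark_percentiles, mask)
    if np.any(np.diff(src) <= 0):
        # collapse duplicate landmarks by keeping the strictly increasing subset
        keep = np.concatenate([[True], np.diff(src) > 0])
        src_k = src[keep]
        dst_k = np.asarray(template.landmark_values)[keep]
        if src_k.size < 2:
            raise ValueError("volume landmarks are degenerate")
    else:
        src_k, dst_k = src, np.asarray(template.landmark_values)
    mapped = piecewise_linear_map(volume.array, src_k, dst_k)
    return volume.with_array(mapped)


def resample_mask_nn(mask: RoiMask, target_shape: Sequence[int],
                     target_spacing: Sequence[float],
                     target_origin_mm: Sequence[float] = (0.0, 0.0, 0.0)
                     ) -> RoiMask:
    """Nearest-neighbor resample of a binary mask onto a new grid.

    The source grid has voxel centers at ``i * spacing`` (origin 0); the
    target grid at ``origin + i * spacing``. A target voxel takes the value
    of the source voxel whose center is nearest (i.e. the source voxel
    containing the target center).
    """
    target_shape = tuple(int(s) for s in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    src = mask.array
    out = np.zeros(target_shape, dtype=bool)

    idx = []
    any_overlap = True
    for ax in range(3):
        centers_mm = (float(target_origin_mm[ax])
                      + np.arange(target_shape[ax]) * target_spacing[ax])
        # conventional round-half-up to the nearest source voxel center
        i_src = np.floor(centers_mm / mask.spacing_mm[ax] + 0.5).astype(int)
        inside = (i_src >= 0) & (i_src < src.shape[ax])
        if not inside.any():
            any_overlap = False
        idx.append((i_src, inside))
    if not any_overlap:
        raise ValueError("target grid does not overlap the source grid")

    ix, okx = idx[0]
    iy, oky = idx[1]
    iz, okz = idx[2]
    valid = okx[:, None, None] & oky[None, :, None] & okz[None, None, :]
    gx = np.clip(ix, 0, src.shape[0] - 1)
    gy = np.clip(iy, 0, src.shape[1] - 1)
    gz = np.clip(iz, 0, src.shape[2] - 1)
    out = src[np.ix_(gx, gy, gz)] & valid

    result = RoiMask(out, target_spacing, patient_id=mask.patient_id,
                     timepoint=mask.timepoint)
    result.empty_after_resample = not out.any()  # type: ignore[attr-defined]
    return result
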