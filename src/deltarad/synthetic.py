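"""Synthetic serial bi-parametric pseudo-MRI cohort with known progression signal.

Emulates a two-arm active-surveillance cohort: every patient has a baseline and
a follow-up scan pair (T2W-like and ADC-like volumes plus a lesion mask) and a
clinical record (PSA, tumor volume, age, PIRADS, upgrade label). Patients in
the upgrade arm (AS+) change lesion texture heterogeneity between timepoints —
the correlation length and amplitude of a Gaussian random field are multiplied
by configurable effects — and have larger PSA / tumor-volume increases, while
no-upgrade (AS−) follow-up lesions are fresh draws from the baseline texture
distribution. Generation is a pure function of :class:`CohortConfig`.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import ImageVolume, RoiMask, save_nifti, load_volume, load_mask

PIRADS_LEVELS = (3, 4, 5)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Effects are expressed as multiplicative texture changes applied at
    follow-up in AS+ lesions only (``delta_*_effect``) and standardized
    between-arm differences (Cohen's d) on the clinical deltas.
    """

    n_patients: int = 30
    prevalence_pos: float = 19 / 30
    grid_shape: Tuple[int, int, int] = (48, 48, 16)
    voxel_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radius_mm: float = 6.0
    texture_corr_len_mm: float = 2.0
    texture_sd: float = 12.0
    delta_corr_len_effect: float = 1.3
    delta_sd_effect: float = 1.3
    lesion_growth_factor: float = 1.15
    psa_baseline_mean: float = 5.5      # ng/ml
    psa_baseline_sd: float = 2.0        # ng/ml
    delta_psa_effect_d: float = 0.8
    volume_effect_d: float = 0.8
    noise_sd: float = 3.0
    seed: int = 0
    # between-patient biological variability of the texture parameters
    # (log-normal sd on the per-scan texture sd / correlation length)
    texture_sd_jitter_log: float = 0.15
    texture_corr_jitter_log: float = 0.10
    # secondary appearance knobs (rarely touched)
    background_mean: float = 120.0
    background_texture_sd: float = 6.0
    background_corr_len_mm: float = 4.0
    lesion_offset_t2w: float = -20.0
    followup_gain_log_sd: float = 0.08  # T2W scanner intensity drift
    adc_mean: float = 1400.0
    adc_inversion_slope: float = 4.0
    adc_lesion_offset: float = -350.0
    adc_noise_sd: float = 40.0
    delta_psa_base_mean: float = 0.8    # AS− mean PSA change, ng/ml
    delta_psa_sd: float = 1.5
    delta_volume_base_mean: float = 0.05  # AS− mean volume change, cc
    delta_volume_sd: float = 0.3
    pirads_probs_neg_bl: Tuple[float, float, float] = (0.55, 0.35, 0.10)
    pirads_probs_pos_bl: Tuple[float, float, float] = (0.45, 0.45, 0.10)
    pirads_probs_neg_fu: Tuple[float, float, float] = (0.50, 0.35, 0.15)
    pirads_probs_pos_fu: Tuple[float, float, float] = (0.20, 0.45, 0.35)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_pos < 1.0:
            raise ValueError("prevalence_pos must lie strictly in (0, 1)")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape dimensions must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be positive")
        for name in ("lesion_radius_mm", "texture_corr_len_mm",
                     "delta_corr_len_effect", "delta_sd_effect",
                     "lesion_growth_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.texture_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        n_pos = self.n_positive
        if n_pos == 0 or n_pos == self.n_patients:
            raise ValueError(
                f"prevalence {self.prevalence_pos} leaves an empty arm for "
                f"n={self.n_patients}")

    @property
    def n_positive(self) -> int:
        # round-half-up so e.g. 30 * 0.63... -> 19
        return int(np.floor(self.n_patients * self.prevalence_pos + 0.5))


def null_effects(config: CohortConfig) -> CohortConfig:
    """Zero every between-arm effect (null cohort for calibration checks)."""
    return replace(
        config,
        delta_corr_len_effect=1.0,
        delta_sd_effect=1.0,
        lesion_growth_factor=1.0,
        delta_psa_effect_d=0.0,
        volume_effect_d=0.0,
        pirads_probs_pos_bl=config.pirads_probs_neg_bl,
        pirads_probs_pos_fu=config.pirads_probs_neg_fu,
    )


def delta_texture_condition(config: CohortConfig) -> CohortConfig:
    """Delta-only texture effects: identical lesion geometry at both
    timepoints, so the imaging signal is carried purely by the follow-up
    texture change (clinical deltas keep their configured effects)."""
    return replace(config, lesion_growth_factor=1.0)


@dataclass
class ClinicalRecord:
    patient_id: str
    age: int
    psa_bl: float
    psa_fu: float
    volume_bl: float
    volume_fu: float
    pirads_bl: int
    pirads_fu: int
    label: int  # 1 = AS+ (upgrade), 0 = AS−

CLINICAL_COLUMNS = ["patient_id", "age", "psa_bl", "psa_fu", "volume_bl",
                    "volume_fu", "pirads_bl", "pirads_fu", "label"]


@dataclass
class CohortBundle:
    volumes: Dict[Tuple[str, str, str], ImageVolume]  # (pid, timepoint, sequence)
    masks: Dict[Tuple[str, str], RoiMask]             # (pid, timepoint)
    clinical: List[ClinicalRecord]
    truth: Dict[str, int]
    config: CohortConfig | None = None

    @property
    def patient_ids(self) -> List[str]:
        return [rec.patient_id for rec in self.clinical]

    def clinical_rows(self) -> List[dict]:
        return [dataclasses.asdict(rec) for rec in self.clinical]


def lesion_texture(shape: Sequence[int], corr_len_mm: float, sd: float,
                   seed: int | None = None,
                   spacing_mm: float | Sequence[float] = 1.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Zero-mean Gaussian random field with isotropic correlation length.

    White noise is smoothed with a Gaussian kernel whose sigma equals
    ``corr_len_mm`` (converted to voxels per axis), then rescaled so the
    empirical standard deviation over the field equals ``sd`` exactly.
    """
    shape = tuple(int(s) for s in shape)
    if corr_len_mm <= 0:
        raise ValueError("corr_len_mm must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (len(shape),))
    extents = np.asarray(shape) * spacing
    if corr_len_mm >= extents.min():
        raise ValueError(
            f"corr_len_mm={corr_len_mm} exceeds the field extent {extents.min()}")
    if sd == 0:
        return np.zeros(shape)
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma_vox = corr_len_mm / spacing
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    smooth -= smooth.mean()
    s = smooth.std()
    if s == 0:  # pragma: no cover - only for pathological tiny fields
        raise ValueError("degenerate field: zero variance after smoothing")
    return smooth * (sd / s)


def _sphere_mask(grid_shape: Tuple[int, int, int],
                 spacing: Tuple[float, float, float],
                 center_vox: Tuple[float, float, float],
                 radius_mm: float) -> np.ndarray:
    ax = [(np.arange(n) - c) * s for n, c, s in zip(grid_shape, center_vox, spacing)]
    dist2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
             + ax[2][None, None, :] ** 2)
    return dist2 <= radius_mm ** 2


def _lesion_field(mask: np.ndarray, corr_len_mm: float, sd: float,
                  spacing: Tuple[float, float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Textured field over the lesion bounding box, zero outside the mask."""
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box_shape = tuple(hi - lo)
    field = lesion_texture(box_shape, corr_len_mm, sd, spacing_mm=spacing, rng=rng)
    out = np.zeros(mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    out[sl] = field
    out[~mask] = 0.0
    return out


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full serial cohort; deterministic in ``config`` (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pos = config.n_positive
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]

    spacing = config.voxel_spacing_mm
    nx, ny, nz = config.grid_shape

    volumes: Dict[Tuple[str, str, str], ImageVolume] = {}
    masks: Dict[Tuple[str, str], RoiMask] = {}
    clinical: List[ClinicalRecord] = []
    truth: Dict[str, int] = {}

    # log-normal parameterized to the requested PSA mean/sd (ng/ml)
    cv2 = (config.psa_baseline_sd / config.psa_baseline_mean) ** 2
    sigma_ln = float(np.sqrt(np.log1p(cv2)))
    mu_ln = float(np.log(config.psa_baseline_mean) - 0.5 * sigma_ln ** 2)

    for i in range(n):
        pid = f"P{i:03d}"
        pos = bool(labels[i])
        truth[pid] = int(pos)

        jitter = rng.integers(-2, 3, size=2)
        center = (nx // 2 + jitter[0], ny // 2 + jitter[1], nz // 2)

        radius_fu = config.lesion_radius_mm * (
            config.lesion_growth_factor if pos else 1.0)
        mask_arrs = {
            "baseline": _sphere_mask(config.grid_shape, spacing, center,
                                     config.lesion_radius_mm),
            "followup": _sphere_mask(config.grid_shape, spacing, center, radius_fu),
        }
        gain = float(np.exp(rng.normal(0.0, config.followup_gain_log_sd)))

        for tp in ("baseline", "followup"):
            mask = mask_arrs[tp]
            if pos and tp == "followup":
                corr = config.texture_corr_len_mm * config.delta_corr_len_effect
                sd = config.texture_sd * config.delta_sd_effect
            else:
                corr = config.texture_corr_len_mm
                sd = config.texture_sd
            # between-patient / between-scan biological variability
            corr *= float(np.exp(rng.normal(0.0, config.texture_corr_jitter_log)))
            sd *= float(np.exp(rng.normal(0.0, config.texture_sd_jitter_log)))
            background = lesion_texture(
                config.grid_shape, config.background_corr_len_mm,
                config.background_texture_sd, spacing_mm=spacing, rng=rng)
            lesion = _lesion_field(mask, corr, sd, spacing, rng)

            t2w = (config.background_mean + background + lesion
                   + config.lesion_offset_t2w * mask
                   + rng.normal(0.0, config.noise_sd, size=config.grid_shape))
            if tp == "followup":
                t2w = t2w * gain  # intensity drift, corrected by standardization
            adc = (config.adc_mean + 2.0 * background
                   - config.adc_inversion_slope * lesion
                   + config.adc_lesion_offset * mask
                   + rng.normal(0.0, config.adc_noise_sd, size=config.grid_shape))

            volumes[(pid, tp, "T2W")] = ImageVolume(
                t2w, spacing, sequence="T2W", patient_id=pid, timepoint=tp)
            volumes[(pid, tp, "ADC")] = ImageVolume(
                adc, spacing, sequence="ADC", patient_id=pid, timepoint=tp)
            masks[(pid, tp)] = RoiMask(mask, spacing, patient_id=pid, timepoint=tp)

        age = int(np.clip(round(rng.normal(67, 6)), 50, 82))
        psa_bl = float(np.exp(rng.normal(mu_ln, sigma_ln)))
        d_psa = rng.normal(config.delta_psa_base_mean, config.delta_psa_sd)
        if pos:
            d_psa += config.delta_psa_effect_d * config.delta_psa_sd
        psa_fu = max(0.1, psa_bl + float(d_psa))

        vol_bl = max(0.05, masks[(pid, "baseline")].volume_cc()
                     + float(rng.normal(0.0, 0.1)))
        d_vol = rng.normal(config.delta_volume_base_mean, config.delta_volume_sd)
        if pos:
            d_vol += config.volume_effect_d * config.delta_volume_sd
        vol_fu = max(0.05, vol_bl + float(d_vol))

        p_bl = config.pirads_probs_pos_bl if pos else config.pirads_probs_neg_bl
        p_fu = config.pirads_probs_pos_fu if pos else config.pirads_probs_neg_fu
        pirads_bl = int(rng.choice(PIRADS_LEVELS, p=np.asarray(p_bl) / sum(p_bl)))
        pirads_fu = int(rng.choice(PIRADS_LEVELS, p=np.asarray(p_fu) / sum(p_fu)))

        clinical.append(ClinicalRecord(
            patient_id=pid, age=age, psa_bl=round(psa_bl, 3),
            psa_fu=round(psa_fu, 3), volume_bl=round(vol_bl, 4),
            volume_fu=round(vol_fu, 4), pirads_bl=pirads_bl,
            pirads_fu=pirads_fu, label=int(pos)))

    return CohortBundle(volumes=volumes, masks=masks, clinical=clinical,
                        truth=truth, config=config)


# ---------------------------------------------------------------------------
# On-disk layout


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write NIfTI volumes/masks, the clinical CSV and a manifest JSON.

    Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    image_paths: Dict[str, str] = {}
    mask_paths: Dict[str, str] = {}
    for (pid, tp, seq), vol in sorted(bundle.volumes.items()):
        rel = f"images/{pid}_{tp}_{seq}.nii.gz"
        save_nifti(vol, out / rel)
        image_paths[f"{pid}|{tp}|{seq}"] = rel
    for (pid, tp), mask in sorted(bundle.masks.items()):
        rel = f"masks/{pid}_{tp}_mask.nii.gz"
        save_nifti(mask, out / rel)
        mask_paths[f"{pid}|{tp}"] = rel

    clinical_rel = "clinical.csv"
    with open(out / clinical_rel, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CLINICAL_COLUMNS)
        writer.writeheader()
        for row in bundle.clinical_rows():
            writer.writerow(row)

    manifest = {
        "n_patients": len(bundle.clinical),
        "seed": bundle.config.seed if bundle.config else None,
        "config": dataclasses.asdict(bundle.config) if bundle.config else None,
        "images": image_paths,
        "masks": mask_paths,
        "clinical": clinical_rel,
        "files": sorted(image_paths.values()) + sorted(mask_paths.values())
                 + [clinical_rel],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort(cohort_dir: str | Path) -> CohortBundle:
    """Load a cohort written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)

    config = None
    if manifest.get("config"):
        cfg = dict(manifest["config"])
        for key in ("grid_shape", "voxel_spacing_mm", "pirads_probs_neg_bl",
                    "pirads_probs_pos_bl", "pirads_probs_neg_fu",
                    "pirads_probs_pos_fu"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        config = CohortConfig(**cfg)

    volumes: Dict[Tuple[str, str, str], ImageVolume] = {}
    for key, rel in manifest["images"].items():
        pid, tp, seq = key.split("|")
        volumes[(pid, tp, seq)] = load_volume(root / rel, sequence=seq,
                                              patient_id=pid, timepoint=tp)
    masks: Dict[Tuple[str, str], RoiMask] = {}
    for key, rel in manifest["masks"].items():
        pid, tp = key.split("|")
        masks[(pid, tp)] = load_mask(root / rel, patient_id=pid, timepoint=tp)

    clinical: List[ClinicalRecord] = []
    with open(root / manifest["clinical"], newline="") as fh:
        for row in csv.DictReader(fh):
            clinical.append(ClinicalRecord(
                patient_id=row["patient_id"], age=int(row["age"]),
                psa_bl=float(row["psa_bl"]), psa_fu=float(row["psa_fu"]),
                volume_bl=float(row["volume_bl"]),
                volume_fu=float(row["volume_fu"]),
                pirads_bl=int(row["pirads_bl"]), pirads_fu=int(row["pirads_fu"]),
                label=int(row["label"])))
    truth = {rec.patient_id: rec.label for rec in clinical}
    return CohortBundle(volumes=volumes, masks=masks, clinical=clinical,
                        truth=truth, config=config)
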