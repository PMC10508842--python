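"""End-to-end stages: simulate -> standardize+extract -> evaluate.

Each stage writes standard-format artifacts (NIfTI, CSV, JSON) plus the
config hash of its inputs so a report can be traced back to the cohort that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

from .config import FeatureOptions, PipelineConfig
from .features import delta_features, extract_features, feature_names
from .images import SEQUENCES, TIMEPOINTS
from .model import CvConfig, EvalReport, evaluate_models
from .preprocess import learn_template, standardize
from .synthetic import (CohortBundle, CohortConfig, generate_cohort,
                        read_cohort, write_cohort)

log = logging.getLogger("deltarad")


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_simulate(config: CohortConfig, out_dir: str | Path) -> dict:
    """Generate a cohort and write it to ``out_dir``; returns the manifest."""
    bundle = generate_cohort(config)
    manifest = write_cohort(bundle, out_dir)
    log.info("simulate: %d patients -> %s (config hash %s)",
             config.n_patients, out_dir, _hash_dict(manifest["config"]))
    return manifest


def extract_cohort_features(bundle: CohortBundle,
                            options: FeatureOptions | None = None
                            ) -> Dict[str, pd.DataFrame]:
    """Standardize T2W, extract per-sequence features, build delta tables.

    Returns per-sequence and concatenated bi-parametric tables keyed by
    ``{T2W|ADC|bpmri}_{baseline|followup|delta}``. T2W volumes pass through
    landmark standardization against a template learned from the cohort's
    baseline T2W scans; ADC maps are used as-is (quantitative).
    """
    options = options or FeatureOptions()
    pids = bundle.patient_ids
    complete = []
    for pid in pids:
        have = all((pid, tp, seq) in bundle.volumes
                   for tp in TIMEPOINTS for seq in SEQUENCES) \
            and all((pid, tp) in bundle.masks for tp in TIMEPOINTS)
        if have:
            complete.append(pid)
        else:
            log.warning("patient %s misses a timepoint/sequence: skipped", pid)

    template = learn_template(
        [bundle.volumes[(pid, "baseline", "T2W")] for pid in complete])

    kwargs = dict(n_levels=options.n_levels,
                  haralick_windows=tuple(options.haralick_windows),
                  gabor_wavelength=options.gabor_wavelength,
                  collage_window=options.collage_window,
                  collage_bins=options.collage_bins)

    per_seq: Dict[Tuple[str, str], Dict[str, dict]] = {
        (seq, tp): {} for seq in SEQUENCES for tp in TIMEPOINTS}
    for pid in complete:
        for tp in TIMEPOINTS:
            mask = bundle.masks[(pid, tp)]
            for seq in SEQUENCES:
                vol = bundle.volumes[(pid, tp, seq)]
                assert vol.sequence != "ADC" or seq == "ADC"
                if seq == "T2W":
                    vol = standardize(vol, template)
                per_seq[(seq, tp)][pid] = extract_features(vol, mask, **kwargs)

    tables: Dict[str, pd.DataFrame] = {}
    cols = feature_names()
    for seq in SEQUENCES:
        bl = pd.DataFrame.from_dict(per_seq[(seq, "baseline")], orient="index")[cols]
        fu = pd.DataFrame.from_dict(per_seq[(seq, "followup")], orient="index")[cols]
        delta = pd.DataFrame.from_dict(
            {pid: delta_features(per_seq[(seq, "followup")][pid],
                                 per_seq[(seq, "baseline")][pid])
             for pid in complete}, orient="index")[cols]
        tables[f"{seq}_baseline"] = bl
        tables[f"{seq}_followup"] = fu
        tables[f"{seq}_delta"] = delta

    for tp in ("baseline", "followup", "delta"):
        t2w = tables[f"T2W_{tp}"].add_prefix("t2w__")
        adc = tables[f"ADC_{tp}"].add_prefix("adc__")
        tables[f"bpmri_{tp}"] = pd.concat([t2w, adc], axis=1)
    for tbl in tables.values():
        tbl.index.name = "patient_id"
    return tables


def run_extract(cohort_dir: str | Path, out_dir: str | Path,
                options: FeatureOptions | None = None) -> Dict[str, pd.DataFrame]:
    """Extract feature CSVs from a cohort directory."""
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    bundle = read_cohort(cohort_dir)
    tables = extract_cohort_features(bundle, options)
    out.mkdir(parents=True, exist_ok=True)
    for key, tbl in tables.items():
        tbl.to_csv(out / f"features_{key}.csv", float_format="%.10g")
    clin = pd.DataFrame(bundle.clinical_rows()).set_index("patient_id")
    clin.to_csv(out / "clinical.csv")
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    meta = {"cohort_hash": _hash_dict(manifest),
            "options": (options or FeatureOptions()).model_dump_json(),
            "n_patients": len(clin)}
    with open(out / "extract_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    log.info("extract: %d patients -> %s", len(clin), out)
    return tables


def run_evaluate(features_dir: str | Path, out_dir: str | Path,
                 cv_config: CvConfig) -> EvalReport:
    """Evaluate all five variants plus comparators from extracted CSVs."""
    fdir, out = Path(features_dir), Path(out_dir)
    features = {
        "baseline": pd.read_csv(fdir / "features_bpmri_baseline.csv",
                                index_col="patient_id"),
        "delta": pd.read_csv(fdir / "features_bpmri_delta.csv",
                             index_col="patient_id"),
    }
    clinical = pd.read_csv(fdir / "clinical.csv", index_col="patient_id")
    mismatch = set(features["baseline"].index) ^ set(clinical.index)
    if mismatch:
        raise ValueError(f"patient ids misaligned between features and "
                         f"clinical table: {sorted(mismatch)}")

    report = evaluate_models(features, clinical, cv_config)
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    meta_path = fdir / "extract_meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            d["upstream"] = json.load(fh)
    with open(out / "eval_report.json", "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
    report.to_frame().to_csv(out / "eval_report.csv", index=False)
    counts = []
    for v, vr in report.variants.items():
        for name, c in vr.selected_counts.items():
            counts.append({"variant": v, "feature": name, "times_selected": c})
    pd.DataFrame(counts).to_csv(out / "selected_features.csv", index=False)
    log.info("evaluate: %d variants -> %s", len(report.variants), out)
    return report


def run_all(config: PipelineConfig, work_dir: str | Path) -> EvalReport:
    """Simulate, extract and evaluate under one base seed."""
    work = Path(work_dir)
    cohort_dir = work / config.paths.cohort_dir
    features_dir = work / config.paths.features_dir
    report_dir = work / config.paths.report_dir
    run_simulate(config.cohort.build(config.seed), cohort_dir)
    run_extract(cohort_dir, features_dir, config.features)
    return run_evaluate(features_dir, report_dir, config.cv.build(config.seed))
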