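"""Five-variant random-forest evaluation inside repeated stratified CV.

Model variants (radiomics source + optional clinical covariates):

========  =========================================================
C_br      baseline radiomics
C_brbcl   baseline radiomics + baseline clinical (PSA, tumor volume)
C_dr      delta radiomics
C_drbcl   delta radiomics + baseline clinical
C_drdcl   delta radiomics + delta clinical
========  =========================================================

Within every training fold only: constant/correlated features are pruned,
mRMR picks ``mrmr_k`` features, and a random forest is fitted. Integrated
variants stack a second-stage forest on the first stage's out-of-bag risk
score plus the clinical covariates. Each run pools its test-fold scores into
one AUC; the report carries mean +/- sd across runs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .selection import mrmr_select, prune_correlated, wilcoxon_rank_sum

VARIANTS: Dict[str, Tuple[str, str | None]] = {
    "C_br": ("baseline", None),
    "C_brbcl": ("baseline", "baseline"),
    "C_dr": ("delta", None),
    "C_drbcl": ("delta", "baseline"),
    "C_drdcl": ("delta", "delta"),
}

#: the clinically significant covariates used by the integrated variants
CLINICAL_COVARIATES: Tuple[str, str] = ("psa", "volume")

_MOD = 2 ** 31 - 1


@dataclass(frozen=True)
class CvConfig:
    n_runs: int = 100
    n_folds: int = 3
    rf_trees: int = 500
    stage2_trees: int = 200
    mrmr_k: int = 5
    prune_threshold: float = 0.90
    seed: int = 0
    select_within_folds: bool = True  # False reproduces the optimistic protocol

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.prune_threshold <= 1:
            raise ValueError("prune_threshold must lie in (0, 1]")
        if self.n_runs < 1 or self.rf_trees < 1 or self.mrmr_k < 1:
            raise ValueError("counts must be positive")


# ---------------------------------------------------------------------------
# Scoring primitives


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied score pairs count 1/2."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _confusion_rates(scores: np.ndarray, y: np.ndarray,
                     threshold: float) -> Dict[str, float]:
    pred = scores >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())

    def _rate(num: int, den: int) -> float:
        return num / den if den else 0.0

    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "ppv": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
    }


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed score values; ties in J resolve to
    the lower threshold.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    best_t, best_j = None, -np.inf
    for t in np.unique(s):               # ascending -> ties keep the lower t
        m = _confusion_rates(s, y, t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def metrics_at_threshold(scores: Sequence[float], labels: Sequence[int],
                         threshold: float | None = None) -> Dict[str, float]:
    """Confusion-matrix rates at ``score >= threshold`` (default: Youden)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    if threshold is None:
        threshold = youden_threshold(s, y)
    out = _confusion_rates(s, y, threshold)
    out["threshold"] = float(threshold)
    return out


def metrics_at_sensitivity(scores: Sequence[float], labels: Sequence[int],
                           target: float = 0.90) -> Dict[str, float]:
    """Specificity/PPV/NPV at the largest threshold reaching the target
    sensitivity."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    chosen = None
    for t in np.unique(s)[::-1]:         # descending: largest qualifying t
        if _confusion_rates(s, y, t)["sensitivity"] >= target:
            chosen = float(t)
            break
    flagged = chosen is None
    if chosen is None:                   # unreachable target: lowest threshold
        chosen = float(np.min(s))
    m = _confusion_rates(s, y, chosen)
    return {"specificity": m["specificity"], "ppv": m["ppv"], "npv": m["npv"],
            "sensitivity": m["sensitivity"], "threshold": chosen,
            "target_unreachable": float(flagged)}


# ---------------------------------------------------------------------------
# Random forest stages


def train_rf(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int,
             oob: bool = False) -> RandomForestClassifier:
    """Bagged decision-tree ensemble returning class-1 probabilities."""
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        oob_score=oob, random_state=seed % _MOD, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny folds can leave rows out of bag
        rf.fit(np.asarray(X, dtype=np.float64), y)
    return rf


def _oob_scores(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    oob = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    if np.isnan(oob).any():
        fallback = rf.predict_proba(X)[:, list(rf.classes_).index(1)]
        oob = np.where(np.isnan(oob), fallback, oob)
    return oob


@dataclass
class FoldModel:
    """Everything fitted on one training fold (never sees test data)."""

    retained: List[str]
    selected: List[str]
    columns: List[int]
    rf: RandomForestClassifier
    stage2: RandomForestClassifier | None = None

    def predict(self, X_te: np.ndarray,
                clin_te: np.ndarray | None = None) -> np.ndarray:
        p1 = self.rf.predict_proba(np.asarray(X_te)[:, self.columns])
        p1 = p1[:, list(self.rf.classes_).index(1)]
        if self.stage2 is None:
            return p1
        Z = np.column_stack([p1, clin_te])
        p2 = self.stage2.predict_proba(Z)
        return p2[:, list(self.stage2.classes_).index(1)]


def fit_fold(X_tr: np.ndarray, y_tr: np.ndarray, names: Sequence[str],
             config: CvConfig, seed: int,
             clin_tr: np.ndarray | None = None,
             preselected: Sequence[str] | None = None) -> FoldModel:
    """Prune, select and fit on a training fold only."""
    names = list(names)
    if preselected is None:
        retained = prune_correlated(X_tr, names, config.prune_threshold)
        ret_idx = [names.index(nm) for nm in retained]
        selected = mrmr_select(X_tr[:, ret_idx], y_tr, retained, config.mrmr_k)
    else:
        retained = list(preselected)
        selected = list(preselected)
    columns = [names.index(nm) for nm in selected]
    need_oob = clin_tr is not None
    rf = train_rf(X_tr[:, columns], y_tr, config.rf_trees, seed, oob=need_oob)
    stage2 = None
    if clin_tr is not None:
        risk = _oob_scores(rf, X_tr[:, columns])
        Z = np.column_stack([risk, clin_tr])
        stage2 = train_rf(Z, y_tr, config.stage2_trees, seed + 1)
    return FoldModel(retained=retained, selected=selected, columns=columns,
                     rf=rf, stage2=stage2)


# ---------------------------------------------------------------------------
# Cross-validation protocol


@dataclass
class VariantResult:
    auc_mean: float
    auc_sd: float
    auc_runs: List[float]
    youden_mean: Dict[str, float]
    youden_sd: Dict[str, float]
    at90_mean: Dict[str, float]
    selected_counts: Dict[str, int]
    n_redrawn_splits: int = 0


def _stratified_splits(y: np.ndarray, n_folds: int, seed: int
                       ) -> Tuple[List[Tuple[np.ndarray, np.ndarray]], int]:
    """Stratified fold splits; re-drawn (rarely) if a fold lacks a class."""
    redraws = 0
    while True:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed + 7919 * redraws) % _MOD)
        splits = list(skf.split(np.zeros_like(y), y))
        ok = all(np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2
                 for tr, te in splits)
        if ok:
            return splits, redraws
        redraws += 1
        if redraws > 50:
            raise ValueError("cannot stratify: a class is too small")


def cross_validate(variant: str, features: Dict[str, pd.DataFrame],
                   clinical: pd.DataFrame, config: CvConfig,
                   collect_details: bool = False) -> VariantResult:
    """Repeated stratified k-fold evaluation of one model variant.

    Parameters
    ----------
    features : mapping with keys "baseline" and "delta", each a DataFrame of
        radiomic features indexed by patient_id.
    clinical : DataFrame indexed by patient_id with columns ``psa_bl``,
        ``psa_fu``, ``volume_bl``, ``volume_fu`` and ``label``.
    """
    radiomics_src, clinical_src = VARIANTS[variant]
    F = features[radiomics_src]
    ids = list(F.index)
    if list(clinical.index) != ids:
        clinical = clinical.loc[ids]
    X = F.to_numpy(dtype=np.float64)
    names = list(F.columns)
    y = clinical["label"].to_numpy(dtype=int)

    clin_mat = None
    if clinical_src == "baseline":
        clin_mat = clinical[["psa_bl", "volume_bl"]].to_numpy(dtype=np.float64)
    elif clinical_src == "delta":
        clin_mat = np.column_stack([
            clinical["psa_fu"].to_numpy(float) - clinical["psa_bl"].to_numpy(float),
            clinical["volume_fu"].to_numpy(float) - clinical["volume_bl"].to_numpy(float)])

    preselected = None
    if not config.select_within_folds:   # optimistic protocol (whole-cohort selection)
        retained = prune_correlated(X, names, config.prune_threshold)
        ret_idx = [names.index(nm) for nm in retained]
        preselected = mrmr_select(X[:, ret_idx], y, retained, config.mrmr_k)

    auc_runs: List[float] = []
    youden_rows: List[Dict[str, float]] = []
    at90_rows: List[Dict[str, float]] = []
    counts: Counter = Counter()
    n_redrawn = 0
    details: List[dict] = []

    for r in range(config.n_runs):
        seed_r = (config.seed + r) % _MOD
        splits, redraws = _stratified_splits(y, config.n_folds, seed_r)
        n_redrawn += redraws
        scores = np.empty(y.size)
        for tr, te in splits:
            fm = fit_fold(X[tr], y[tr], names, config, seed_r,
                          clin_tr=None if clin_mat is None else clin_mat[tr],
                          preselected=preselected)
            scores[te] = fm.predict(X[te],
                                    None if clin_mat is None else clin_mat[te])
            counts.update(fm.selected)
            if collect_details:
                details.append({"run": r, "train": tr.tolist(),
                                "selected": fm.selected,
                                "retained": fm.retained})
        auc_runs.append(auc(scores, y))
        youden_rows.append(metrics_at_threshold(scores, y))
        at90_rows.append(metrics_at_sensitivity(scores, y))

    def _agg(rows: List[Dict[str, float]], stat) -> Dict[str, float]:
        keys = [k for k in rows[0] if k not in ("threshold",)]
        return {k: float(stat([row[k] for row in rows])) for k in keys}

    result = VariantResult(
        auc_mean=float(np.mean(auc_runs)),
        auc_sd=float(np.std(auc_runs)),
        auc_runs=[float(a) for a in auc_runs],
        youden_mean=_agg(youden_rows, np.mean),
        youden_sd=_agg(youden_rows, np.std),
        at90_mean=_agg(at90_rows, np.mean),
        selected_counts=dict(counts.most_common()),
        n_redrawn_splits=n_redrawn,
    )
    if collect_details:
        result.details = details  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# Clinical comparators and the full report


def clinical_comparators(clinical: pd.DataFrame) -> Dict[str, float]:
    """Single-variable rank AUCs of the routine clinical markers."""
    y = clinical["label"].to_numpy(int)
    psa_d = clinical["psa_fu"] - clinical["psa_bl"]
    vol_d = clinical["volume_fu"] - clinical["volume_bl"]
    pir_d = clinical["pirads_fu"] - clinical["pirads_bl"]
    return {
        "psa_baseline": auc(clinical["psa_bl"], y),
        "volume_baseline": auc(clinical["volume_bl"], y),
        "pirads_baseline": auc(clinical["pirads_bl"], y),
        "delta_psa": auc(psa_d, y),
        "delta_volume": auc(vol_d, y),
        "delta_pirads": auc(pir_d, y),
    }


@dataclass
class EvalReport:
    variants: Dict[str, VariantResult]
    comparators: Dict[str, float]
    top_features: Dict[str, List[dict]]
    config: CvConfig

    def to_dict(self) -> dict:
        d = {
            "config": dataclasses.asdict(self.config),
            "comparators": self.comparators,
            "top_features": self.top_features,
            "variants": {},
        }
        for name, vr in self.variants.items():
            d["variants"][name] = {
                "auc_mean": vr.auc_mean, "auc_sd": vr.auc_sd,
                "youden_mean": vr.youden_mean, "youden_sd": vr.youden_sd,
                "at90_mean": vr.at90_mean,
                "selected_counts": dict(
                    Counter(vr.selected_counts).most_common(20)),
                "n_redrawn_splits": vr.n_redrawn_splits,
            }
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, vr in self.variants.items():
            rows.append({"variant": name, "metric": "auc",
                         "mean": vr.auc_mean, "sd": vr.auc_sd})
            for k, v in vr.youden_mean.items():
                rows.append({"variant": name, "metric": k, "mean": v,
                             "sd": vr.youden_sd[k]})
            for k, v in vr.at90_mean.items():
                rows.append({"variant": name, "metric": f"{k}_at90sens",
                             "mean": v, "sd": np.nan})
        for k, v in self.comparators.items():
            rows.append({"variant": k, "metric": "auc_univariate",
                         "mean": v, "sd": np.nan})
        return pd.DataFrame(rows)


def evaluate_models(features: Dict[str, pd.DataFrame], clinical: pd.DataFrame,
                    config: CvConfig,
                    variants: Sequence[str] | None = None) -> EvalReport:
    """Run every model variant plus the clinical comparators."""
    if variants is None:
        variants = list(VARIANTS)
    ids = list(features["baseline"].index)
    missing = [i for i in ids if i not in clinical.index]
    if missing:
        raise ValueError(f"clinical table is missing patients: {missing}")
    clinical = clinical.loc[ids]

    results = {v: cross_validate(v, features, clinical, config)
               for v in variants}

    top: Dict[str, List[dict]] = {}
    y = clinical["label"].to_numpy(int)
    for v, vr in results.items():
        src = VARIANTS[v][0]
        F = features[src]
        entries = []
        for name, count in Counter(vr.selected_counts).most_common(3):
            col = F[name].to_numpy(float)
            p = wilcoxon_rank_sum(col[y == 1], col[y == 0])
            entries.append({"feature": name, "times_selected": count,
                            "wilcoxon_p": p})
        top[v] = entries

    return EvalReport(variants=results,
                      comparators=clinical_comparators(clinical),
                      top_features=top, config=config)
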