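# deltarad

Delta radiomics on serial bi-parametric prostate MRI for predicting
pathologic upgrade in men on active surveillance.

Men with low-risk prostate cancer are monitored (active surveillance, AS)
rather than treated, with repeat biopsies as the costly, invasive gold
standard for detecting progression. This package implements a pipeline that
asks whether the *change* in quantitative lesion texture between a baseline
and a follow-up MRI — "delta radiomics", ΔF = F(follow-up) − F(baseline) —
combined with changes in routine clinical variables (PSA, tumor volume),
predicts biopsy upgrade (AS+) better than baseline imaging or clinical
scores alone. Because no patient data are released for this problem, the
package ships a synthetic serial-MRI cohort generator with a known,
configurable progression signal, and every stage is tested against it.

The pipeline:

* **Cohort**: paired T2W/ADC pseudo-MRI volumes + lesion masks + clinical
  table for a two-arm cohort (default 30 patients, 19 AS+), where AS+
  lesions change texture heterogeneity at follow-up.
* **Preprocessing**: landmark (decile) histogram standardization of T2W
  against a cohort template; ADC is quantitative and never standardized.
* **Features**: 252 per sequence and timepoint — 18 slice-level first-order
  statistics and 45 per-voxel texture maps (13 Haralick co-occurrence
  statistics at 3×3/5×5/7×7 windows, 5 Gabor orientations, CoLlAGe
  gradient-orientation entropy), each summarized over the lesion by mean,
  variance, skewness and kurtosis.
* **Models**: Pearson pruning (|r| ≥ 0.90), mRMR selection, random forests
  for five variants — baseline radiomics (C_br), + baseline clinical
  (C_brbcl), delta radiomics (C_dr), + baseline clinical (C_drbcl),
  + delta clinical (C_drdcl) — inside 100 runs of stratified threefold
  cross-validation, reporting rank AUC (mean ± sd), metrics at the Youden
  threshold and at 90 % sensitivity, and feature-selection frequencies.

## Worked example

```python
import pandas as pd
import deltarad as dr
from deltarad.pipeline import extract_cohort_features
from deltarad.model import CvConfig, cross_validate
from deltarad.synthetic import delta_texture_condition

# 30 patients; AS+ lesions change texture at follow-up, geometry fixed
cfg = delta_texture_condition(dr.CohortConfig(seed=3))
bundle = dr.generate_cohort(cfg)
tables = extract_cohort_features(bundle)           # standardize + extract
feats = {"baseline": tables["bpmri_baseline"],     # 30 x 504
         "delta": tables["bpmri_delta"]}
clin = pd.DataFrame(bundle.clinical_rows()).set_index("patient_id")

cv = CvConfig(n_runs=25, rf_trees=150, stage2_trees=75, seed=0)
for v in ("C_br", "C_dr", "C_drdcl"):
    r = cross_validate(v, feats, clin, cv)
    print(f"{v}: AUC {r.auc_mean:.3f} +/- {r.auc_sd:.3f}")
```

prints (one fixed seed):

```
C_br: AUC 0.489 +/- 0.110
C_dr: AUC 0.609 +/- 0.095
C_drdcl: AUC 0.765 +/- 0.046
```

Baseline radiomics carry no signal by construction (the arms share one
baseline distribution, so C_br hovers at chance), delta radiomics recover
the follow-up texture change, and stacking the delta clinical variables on
the delta-radiomics risk score improves the AUC further — the qualitative
ordering the pipeline is designed to detect.

The same stages are available as a CLI (`deltarad simulate / standardize /
extract / evaluate / report`, YAML-configured) and as numbered drivers under
`analysis/` that write their tables to `results/`.

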