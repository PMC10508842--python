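"""Standardize T2W and extract radiomic feature tables.

Reads the cohort written by 01_simulate_cohort.py, learns the T2W landmark
template from baseline scans, extracts the 252-feature vectors per sequence
and timepoint, forms delta tables, and writes the CSVs under
scratch/features (they are inputs to 03, not end results). A small sanity
summary of the delta-feature separation goes to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from deltarad.pipeline import run_extract
from deltarad.selection import wilcoxon_rank_sum

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "scratch" / "cohort"
    out = ROOT / "scratch" / "features"
    tables = run_extract(cohort, out)
    delta = tables["bpmri_delta"]
    clin = pd.read_csv(out / "clinical.csv", index_col="patient_id")
    y = clin.loc[delta.index, "label"].to_numpy(int)

    rows = []
    for name in delta.columns:
        col = delta[name].to_numpy(float)
        p = wilcoxon_rank_sum(col[y == 1], col[y == 0])
        rows.append({"feature": name, "wilcoxon_p": p})
    tab = pd.DataFrame(rows).sort_values("wilcoxon_p").head(15)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    tab.to_csv(res / "top_delta_features.csv", index=False)
    n_sig = int((pd.DataFrame(rows).wilcoxon_p < 0.05).sum())
    print(f"delta table: {delta.shape[0]} patients x {delta.shape[1]} features")
    print(f"{n_sig} delta features separate the arms at p < 0.05")
    print(tab.to_string(index=False))


if __name__ == "__main__":
    main()
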