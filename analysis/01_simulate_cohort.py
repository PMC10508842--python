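"""Simulate the synthetic active-surveillance cohort.

Generates the default 30-patient serial bpMRI cohort (19 upgraders / 11
non-upgraders, two timepoints, T2W + ADC + lesion masks), writes the NIfTI
tree under scratch/ and a small per-arm clinical summary under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import deltarad as dr

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    cfg = dr.CohortConfig(seed=seed)
    out = ROOT / "scratch" / "cohort"
    manifest = dr.write_cohort(dr.generate_cohort(cfg), out)
    print(f"wrote {len(manifest['files'])} files to {out}")

    clin = pd.read_csv(out / "clinical.csv")
    clin["delta_psa"] = clin.psa_fu - clin.psa_bl
    clin["delta_volume"] = clin.volume_fu - clin.volume_bl
    summary = clin.groupby("label")[
        ["age", "psa_bl", "delta_psa", "volume_bl", "delta_volume",
         "pirads_bl", "pirads_fu"]].agg(["mean", "std"]).round(3)
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    summary.to_csv(res / "cohort_clinical_summary.csv")
    print(summary)
    print(f"arm sizes: AS+={int(clin.label.sum())}, "
          f"AS-={int((1 - clin.label).sum())}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
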