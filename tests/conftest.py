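import numpy as np
import pandas as pd
import pytest

import deltarad as dr
from deltarad.pipeline import extract_cohort_features


def tiny_config(**overrides) -> dr.CohortConfig:
    """A small, fast cohort: 8 patients, 4 mm lesions on a 32x32x10 grid."""
    base = dict(n_patients=8, prevalence_pos=0.5, grid_shape=(32, 32, 10),
                voxel_spacing_mm=(1.0, 1.0, 3.0), lesion_radius_mm=4.0,
                seed=11)
    base.update(overrides)
    return dr.CohortConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    return dr.generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_tables(tiny_bundle):
    return extract_cohort_features(tiny_bundle)


@pytest.fixture(scope="session")
def tiny_eval_inputs(tiny_bundle, tiny_tables):
    feats = {"baseline": tiny_tables["bpmri_baseline"],
             "delta": tiny_tables["bpmri_delta"]}
    clin = pd.DataFrame(tiny_bundle.clinical_rows()).set_index("patient_id")
    return feats, clin


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
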