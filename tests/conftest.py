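import numpy as np
import pandas as pd
import pytest

from csfmet.io import FeatureTable, InjectionMeta
from csfmet.synth import SynthConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_synth():
    """One modest synthetic data set shared by read-only tests."""
    cfg = SynthConfig(seed=7, n_features=200)
    t1, t2, meta, truth = generate_cohorts(cfg)
    return cfg, t1, t2, meta, truth


@pytest.fixture
def tiny_table():
    """3 features x 4 injections with one missing cell."""
    feats = pd.DataFrame(
        {"mz": [100.0, 200.0, 300.0], "rt": [60.0, 120.0, 180.0],
         "ion_mode": ["positive", "negative", "positive"]},
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"))
    vals = pd.DataFrame(
        [[10.0, 11.0, 12.0, 13.0],
         [20.0, np.nan, 22.0, 23.0],
         [30.0, 31.0, 32.0, 33.0]],
        index=feats.index, columns=["i1", "i2", "i3", "i4"])
    return FeatureTable(feats, vals, "raw")


def make_meta(rows):
    df = pd.DataFrame(rows).set_index("injection_id")
    for col, default in [("subject_id", "pool"), ("group", None),
                         ("dilution_volume", None), ("age", np.nan), ("sex", None),
                         ("timepoint_months", np.nan), ("treated", False)]:
        if col not in df:
            df[col] = default
    return InjectionMeta(df)
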