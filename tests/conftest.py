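import numpy as np
import pandas as pd
import pytest

from fecanet import FeatureTable, SimulationConfig, simulate_study


def make_table(values, sample_meta=None, feature_meta=None):
    """Build a FeatureTable from a features × samples array.

    Default metadata: samples named S1.. with two participants × two
    drills plus pools for any extra columns; features F1.. polar level 1.
    """
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if sample_meta is None:
        rows = []
        n_study = n_samp - 2 if n_samp >= 4 else 0
        for j in range(n_samp):
            if j < n_study:
                part = "V%d" % (j // 2 + 1)
                rows.append(("S%d" % (j + 1), part, j % 2 + 1, "study"))
            else:
                rows.append(("S%d" % (j + 1), np.nan, np.nan, "pool"))
        sample_meta = pd.DataFrame(
            rows, columns=["sample_id", "participant_id", "drill_area",
                           "sample_type"])
        sample_meta["drill_area"] = sample_meta["drill_area"].astype("Int64")
    if feature_meta is None:
        feature_meta = pd.DataFrame({
            "feature_id": ["F%d" % (i + 1) for i in range(n_feat)],
            "name": ["feat %d" % (i + 1) for i in range(n_feat)],
            "platform": ["polar"] * n_feat,
            "compound_class": ["amino acid"] * n_feat,
            "annotation_level": [1] * n_feat,
            "is_internal_standard": [False] * n_feat,
        })
    mat = pd.DataFrame(values,
                       index=feature_meta["feature_id"].to_numpy(),
                       columns=sample_meta["sample_id"].to_numpy())
    return FeatureTable(mat, sample_meta, feature_meta)


@pytest.fixture(scope="session")
def small_study():
    """Compact simulated study: fast, but with all design elements."""
    cfg = SimulationConfig(
        n_polar=30, n_lipid=20, n_unknowns=40, network_size=10,
        seed=123,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def reference_design_study():
    """Reference design simulation: 10×4 + 8 pools, 298 annotated features."""
    cfg = SimulationConfig(n_unknowns=1, seed=20)
    return simulate_study(cfg)
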