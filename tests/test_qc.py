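import numpy as np
import pytest

from fecanet import (
    filter_by_missingness,
    filter_by_pool_rsd,
    filter_unknowns,
    knn_impute,
    rsd,
)
from fecanet.errors import ConfigurationError, InsufficientDataError

from _oracles import knn_impute_bruteforce
from conftest import make_table


# ------------------------------------------------------------------- rsd
def test_rsd_hand_values():
    assert rsd([5, 5, 5, 5]) == 0.0
    assert rsd([1, 2, 3]) == pytest.approx(50.0)  # sd 1 (n−1), mean 2
    assert rsd([2, 4, 6]) == pytest.approx(50.0)  # scale invariance


def test_rsd_errors():
    with pytest.raises(InsufficientDataError):
        rsd([1.0])
    with pytest.raises(ZeroDivisionError):
        rsd([-1.0, 1.0])


# --------------------------------------------------------------- filters
def level_table(levels, values=None):
    t = make_table(np.ones((len(levels), 4)) if values is None else values)
    t.features["annotation_level"] = levels
    return t


def test_filter_unknowns_counts():
    t = level_table([1, 4, 2, 4, 3])
    out = filter_unknowns(t)
    assert out.n_features == 3
    assert "F2" not in out.feature_ids
    # idempotent; identity when no level-4 present
    assert filter_unknowns(out).n_features == 3


def test_filter_unknowns_all_level4_gives_empty():
    out = filter_unknowns(level_table([4, 4]))
    assert out.n_features == 0


def test_pool_rsd_boundary_strictness():
    import pandas as pd

    # three pools with symmetric deviations give exactly representable
    # RSDs: (70, 100, 130) -> sd 30, mean 100 -> exactly 30 %
    samples = pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4", "S5"],
        "participant_id": ["V1", "V1", None, None, None],
        "drill_area": pd.array([1, 2, None, None, None], dtype="Int64"),
        "sample_type": ["study", "study", "pool", "pool", "pool"],
    })
    vals = np.array([
        [1.0, 1.0, 70.0, 100.0, 130.0],   # RSD exactly 30 % — kept
        [1.0, 1.0, 60.0, 100.0, 140.0],   # RSD 40 % — excluded
        [1.0, 1.0, 100.0, 100.0, 100.0],  # constant — kept
    ])
    t = make_table(vals, sample_meta=samples)
    got = filter_by_pool_rsd(t, threshold=30.0)
    assert "F1" in got.feature_ids
    assert "F2" not in got.feature_ids
    assert "F3" in got.feature_ids


def test_pool_rsd_unverifiable_features_excluded():
    vals = np.array([[1, 1, np.nan, 5.0], [1, 1, 4.0, 5.0]])
    t = make_table(vals)
    out = filter_by_pool_rsd(t)
    assert out.feature_ids == ["F2"]


def test_pool_rsd_requires_pools():
    t = make_table(np.ones((2, 3)))  # 3 samples → all pools in fixture
    t2 = t.subset_samples(["S1"])
    with pytest.raises(ConfigurationError):
        filter_by_pool_rsd(t2)


def test_missingness_boundary():
    vals = np.ones((3, 10))
    vals[1, :2] = np.nan  # 20 % — kept (strictly "more than")
    vals[2, :3] = np.nan  # 30 % — removed
    samples = make_table(np.ones((1, 10))).samples
    t = make_table(vals, sample_meta=samples)
    out = filter_by_missingness(t, max_fraction=0.20)
    assert out.feature_ids == ["F1", "F2"]


def test_missingness_all_missing_removed():
    vals = np.array([[np.nan] * 4, [1.0, 2, 3, 4]])
    out = filter_by_missingness(make_table(vals))
    assert out.feature_ids == ["F2"]


# ------------------------------------------------------------ imputation
def test_impute_identity_when_complete():
    t = make_table(np.arange(1.0, 13.0).reshape(3, 4))
    out = knn_impute(t, k=2)
    assert out.equals(t)


def test_impute_duplicate_feature_k1():
    """A duplicate fully-observed feature imputes exactly its own value
    (shared means cancel the centering)."""
    vals = np.array([
        [2.0, 4.0, np.nan, 16.0],
        [2.0, 4.0, 8.0, 16.0],
        [100.0, 90.0, 80.0, 70.0],
    ])
    t = make_table(vals)
    out = knn_impute(t, k=1)
    assert out.intensities.loc["F1", "S3"] == pytest.approx(8.0, rel=1e-12)


def test_imputed_values_positive_and_observed_untouched():
    rng = np.random.default_rng(5)
    vals = rng.uniform(1, 100, size=(6, 8))
    mask = rng.random(vals.shape) < 0.15
    mask[:, 0] = False  # keep at least one observed column
    vals[mask] = np.nan
    t = make_table(vals)
    out = knn_impute(t, k=3)
    assert not out.intensities.isna().any().any()
    assert (out.intensities.to_numpy() > 0).all()
    obs = ~np.isnan(vals)
    assert np.array_equal(out.intensities.to_numpy()[obs], vals[obs])


@pytest.mark.parametrize("seed,k", [(0, 1), (1, 2), (2, 3), (3, 2)])
def test_impute_matches_bruteforce_oracle(seed, k):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 50, size=(8, 6))
    mask = rng.random(vals.shape) < 0.1
    vals[mask] = np.nan
    # guarantee every feature retains an observation
    vals[np.isnan(vals).all(axis=1), 0] = 1.0
    t = make_table(vals)
    got = knn_impute(t, k=k).intensities.to_numpy()
    want = knn_impute_bruteforce(vals, k=k)
    assert np.allclose(got, want, atol=1e-10, rtol=0)


def test_impute_rejects_fully_missing_feature():
    vals = np.array([[np.nan] * 4, [1.0, 2, 3, 4]])
    with pytest.raises(InsufficientDataError):
        knn_impute(make_table(vals))


def test_filter_pipeline_counts_reconcile(small_study):
    from fecanet import RunReport, normalize_to_is

    table, _ = small_study
    report = RunReport()
    t = normalize_to_is(table, report=report)
    t = filter_unknowns(t, report=report)
    t = filter_by_pool_rsd(t, report=report)
    t = filter_by_missingness(t, report=report)
    t = knn_impute(t, report=report)
    counts = report.stage_counts
    for (_, _, out_k), (_, in_k1, _) in zip(counts, counts[1:]):
        assert out_k == in_k1
    assert counts[-1][2] == t.n_features
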