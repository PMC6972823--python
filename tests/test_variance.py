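import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fecanet import (
    area_cv,
    bh_adjust,
    feature_f_test,
    participant_cv,
    technical_cv,
    variance_profile,
)
from fecanet.errors import InsufficientDataError

from _oracles import bh_stepup
from conftest import make_table


def study_table(per_participant, pools=(10.0, 10.0)):
    """One feature; per_participant = list of per-participant drill value
    lists; two pool columns appended."""
    values, rows = [], []
    for i, drills in enumerate(per_participant):
        for a, v in enumerate(drills):
            rows.append(("S%d_%d" % (i, a), "V%d" % (i + 1), a + 1, "study"))
            values.append(v)
    for j, v in enumerate(pools):
        rows.append(("P%d" % j, None, None, "pool"))
        values.append(v)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "participant_id", "drill_area",
                       "sample_type"])
    samples["drill_area"] = samples["drill_area"].astype("Int64")
    return make_table(np.array([values]), sample_meta=samples)


def test_technical_cv_hand_values():
    t = study_table([[1, 1], [1, 1]], pools=(90.0, 100.0, 110.0))
    assert technical_cv(t, "F1") == pytest.approx(10.0)
    t2 = study_table([[1, 1]], pools=(10.0, 10.0, 10.0))
    assert technical_cv(t2, "F1") == 0.0


def test_area_cv_hand_values():
    t = study_table([[1, 2, 3], [2, 4, 6]])
    # both participants have within-RSD 50 % -> mean 50 %
    assert area_cv(t, "F1") == pytest.approx(50.0)
    # scaling one participant's drills leaves the number unchanged
    t2 = study_table([[1, 2, 3], [20, 40, 60]])
    assert area_cv(t2, "F1") == pytest.approx(50.0)


def test_participant_cv_hand_values():
    t = study_table([[50, 50], [100, 100], [150, 150]])
    assert participant_cv(t, "F1") == pytest.approx(50.0)
    t0 = study_table([[7, 7], [7, 7]])
    assert participant_cv(t0, "F1") == 0.0


def test_participant_cv_needs_two_participants():
    t = study_table([[1, 2, 3]])
    with pytest.raises(InsufficientDataError):
        participant_cv(t, "F1")


def test_f_equals_squared_t_for_two_groups():
    """With two groups, the unmoderated one-way F equals the squared
    pooled-variance t statistic."""
    rng = np.random.default_rng(8)
    a = np.exp(rng.normal(5, 0.4, size=3))
    b = np.exp(rng.normal(6, 0.4, size=3))
    t = study_table([list(a), list(b)])
    res = feature_f_test(t, moderation="none")
    tt = stats.ttest_ind(np.log(a), np.log(b), equal_var=True)
    assert res["F"].iloc[0] == pytest.approx(tt.statistic**2, rel=1e-10)
    assert res["p"].iloc[0] == pytest.approx(tt.pvalue, rel=1e-10)


def test_f_zero_when_group_means_equal():
    t = study_table([[2.0, 8.0], [8.0, 2.0]])  # same mean per group (logs)
    res = feature_f_test(t, moderation="none")
    assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_constant_feature_flagged_not_error():
    t = study_table([[5.0, 5.0], [5.0, 5.0]])
    res = feature_f_test(t, moderation="none")
    assert res["F"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0


def test_moderation_shrinks_toward_common_variance():
    """Moderated F agrees with the classic F when variances are already
    homogeneous, and the posterior variances have lower spread than the
    raw ones."""
    rng = np.random.default_rng(3)
    vals = np.exp(rng.normal(8, 0.3, size=(200, 12)))
    samples = study_table([[1, 1, 1], [1, 1, 1], [1, 1, 1]],
                          pools=(1, 1, 1)).samples
    t = make_table(vals, sample_meta=samples)
    plain = feature_f_test(t, moderation="none")
    mod = feature_f_test(t, moderation="empirical_bayes")
    r = np.corrcoef(np.log(plain["F"] + 1e-9), np.log(mod["F"] + 1e-9))[0, 1]
    assert r > 0.7
    # moderation adds the prior degrees of freedom to the denominator
    assert (mod["df2"] > plain["df2"]).all()
    # shrinkage: moderated p-values are better calibrated under the null
    assert 0.01 < (mod["p"] < 0.05).mean() < 0.12


def test_bh_hand_stepup():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.2])


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
def test_bh_matches_oracle_and_properties(ps):
    p = np.asarray(ps)
    q = bh_adjust(p)
    assert np.allclose(q, bh_stepup(p), atol=1e-12)
    assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
    # permutation equivariance
    perm = np.random.RandomState(0).permutation(len(p))
    assert np.allclose(bh_adjust(p[perm]), q[perm])


def test_bh_monotone_in_p(small_study):
    from fecanet import knn_impute, filter_by_missingness, filter_unknowns

    table, _ = small_study
    t = knn_impute(filter_by_missingness(filter_unknowns(table)))
    prof = variance_profile(t)
    s = prof.sort_values("p")
    assert s["q"].is_monotonic_increasing


def test_variance_profile_complete_per_platform(small_study):
    from fecanet import knn_impute, filter_by_missingness, filter_unknowns

    table, _ = small_study
    t = knn_impute(filter_by_missingness(filter_unknowns(table)))
    prof = variance_profile(t)
    assert len(prof) == t.n_features
    assert not prof["feature_id"].duplicated().any()
    assert set(prof["platform"]) <= {"polar", "lipid"}
    assert (prof[["cv_technical", "cv_area", "cv_participant"]] >= 0
            ).all().all()


def test_profile_tsv_export(tmp_path, small_study):
    from fecanet import knn_impute, filter_by_missingness, filter_unknowns

    table, _ = small_study
    t = knn_impute(filter_by_missingness(filter_unknowns(table)))
    prof = variance_profile(t, out_dir=str(tmp_path))
    for pf in ("polar", "lipid"):
        got = pd.read_csv(tmp_path / f"variance_{pf}.tsv", sep="\t")
        assert len(got) == (prof["platform"] == pf).sum()


def test_cv_scale_invariance(small_study):
    """All three CVs are invariant to scaling a feature by c > 0."""
    table, _ = small_study
    t = table.copy()
    fid = t.feature_ids[10]
    t.intensities.loc[fid] *= 37.5
    for fn in (technical_cv, area_cv, participant_cv):
        assert fn(t, fid) == pytest.approx(fn(table, fid), rel=1e-9)
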