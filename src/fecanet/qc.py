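"""Quality-control gate: annotation filter, pooled-RSD filter,
missingness filter, and k-nearest-neighbor imputation.

The gate mirrors standard untargeted-metabolomics practice: level-4
(unknown) features are discarded; features whose replicate pooled-QC
injections show a relative standard deviation above 30 % are considered
technically unreliable and discarded; features missing in more than 20 %
of samples are discarded; the remaining missing values are imputed with a
feature-space kNN on log intensities.

Filter order is: unknowns → pool RSD → missingness → imputation.  Each
filter is idempotent.  Pool samples count in the missingness denominator
and participate in imputation (they are injections of the same matrix and
stabilize neighbor distances).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InsufficientDataError
from .io import FeatureTable, RunReport

__all__ = [
    "rsd",
    "filter_unknowns",
    "filter_by_pool_rsd",
    "filter_by_missingness",
    "knn_impute",
    "UnknownsFilter",
    "PoolRSDFilter",
    "MissingnessFilter",
    "FeatureKNNImputer",
]


def rsd(values) -> float:
    """Relative standard deviation, ``100 * sd / mean`` (n−1 sd), in %.

    Computed on the raw linear scale, the analytical-chemistry convention
    for %RSD.  Missing values are ignored; at least two observed values
    and a nonzero mean are required.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError("rsd needs >= 2 non-missing values")
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("rsd undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def _rsd_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise RSD ignoring NaN; NaN where < 2 values or zero mean."""
    obs = ~np.isnan(mat)
    n = obs.sum(axis=1)
    z = np.where(obs, mat, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = z.sum(axis=1) / n
        dev = np.where(obs, mat - mean[:, None], 0.0)
        sd = np.sqrt((dev**2).sum(axis=1) / np.maximum(n - 1, 1))
        out = 100.0 * sd / mean
    out[(n < 2) | (mean == 0)] = np.nan
    return out


class UnknownsFilter(BaseEstimator):
    """Drop level-4 (unknown) features."""

    def fit(self, table: FeatureTable, y=None):
        self.keep_ = list(
            table.features.loc[
                table.features["annotation_level"] != 4, "feature_id"
            ]
        )
        return self

    def transform(
        self, table: FeatureTable, report: RunReport | None = None
    ) -> FeatureTable:
        out = table.subset_features(self.keep_)
        if report is not None:
            report.add_stage("unknowns_filter", table.n_features,
                             out.n_features)
        return out

    def fit_transform(self, table, y=None, report=None):
        return self.fit(table).transform(table, report=report)


class PoolRSDFilter(BaseEstimator):
    """Keep features with pooled-QC RSD ≤ ``threshold`` percent.

    The exclusion is strict ("higher than 30 %"), so a feature exactly at
    the threshold is kept.  Features with fewer than two observed pool
    values cannot be QC'd and are excluded.
    """

    def __init__(self, threshold: float = 30.0):
        self.threshold = threshold

    def fit(self, table: FeatureTable, y=None):
        pools = table.pool_sample_ids()
        if len(pools) < 2:
            raise ConfigurationError("pool-RSD filter needs >= 2 pool samples")
        vals = _rsd_rows(table.intensities[pools].to_numpy())
        self.pool_rsd_ = pd.Series(vals, index=table.feature_ids)
        ok = ~np.isnan(vals) & (vals <= self.threshold)
        self.keep_ = [f for f, k in zip(table.feature_ids, ok) if k]
        return self

    def transform(
        self, table: FeatureTable, report: RunReport | None = None
    ) -> FeatureTable:
        out = table.subset_features(self.keep_)
        if report is not None:
            report.add_stage("pool_rsd_filter", table.n_features,
                             out.n_features)
            report.add_param("rsd_threshold", self.threshold)
        return out

    def fit_transform(self, table, y=None, report=None):
        return self.fit(table).transform(table, report=report)


class MissingnessFilter(BaseEstimator):
    """Drop features missing in more than ``max_fraction`` of samples."""

    def __init__(self, max_fraction: float = 0.20):
        self.max_fraction = max_fraction

    def fit(self, table: FeatureTable, y=None):
        frac = table.intensities.isna().mean(axis=1)
        self.missing_fraction_ = frac
        self.keep_ = list(frac.index[frac <= self.max_fraction])
        return self

    def transform(
        self, table: FeatureTable, report: RunReport | None = None
    ) -> FeatureTable:
        out = table.subset_features(self.keep_)
        if report is not None:
            report.add_stage("missingness_filter", table.n_features,
                             out.n_features)
            report.add_param("max_missing", self.max_fraction)
        return out

    def fit_transform(self, table, y=None, report=None):
        return self.fit(table).transform(table, report=report)


class FeatureKNNImputer(BaseEstimator):
    """Feature-space kNN imputation on log intensities.

    For a missing value of feature *f* in sample *s*:

    1. candidate neighbors are the other features observed in *s* that
       share at least one observed sample with *f*;
    2. the distance to candidate *g* is the mean squared difference of the
       two features' log intensities over their jointly observed samples,
       scaled by the total number of samples (so features compared over
       few samples are not spuriously close);
    3. the *k* nearest candidates (ties broken by feature order) are
       averaged on the centered log scale: each neighbor's log value in
       *s* is shifted by the mean log difference between *f* and that
       neighbor over their jointly observed samples (so a duplicate
       feature imputes exactly its own value), and the shifted values are
       averaged;
    4. with fewer than *k* eligible neighbors all of them are used; with
       none, *f*'s observed mean is used.

    The imputed intensity is the exponential of the imputed log value, so
    it is always strictly positive.  Observed values are never changed.
    """

    def __init__(self, k: int = 10):
        if k < 1:
            raise ValueError("k must be a positive integer")
        self.k = k

    def fit(self, table: FeatureTable, y=None):
        return self

    def transform(
        self, table: FeatureTable, report: RunReport | None = None
    ) -> FeatureTable:
        X = table.intensities.to_numpy(dtype=float)
        obs = ~np.isnan(X)
        if not (obs.any(axis=1)).all():
            bad = np.flatnonzero(~obs.any(axis=1))[0]
            raise InsufficientDataError(
                f"feature {table.feature_ids[bad]!r} has no observed values"
            )
        if obs.all():
            if report is not None:
                report.add_stage("knn_imputation", table.n_features,
                                 table.n_features)
            return table.copy()
        with np.errstate(invalid="ignore"):
            L = np.log(X)
        n_feat, n_samp = L.shape
        means = np.array([L[i, obs[i]].mean() for i in range(n_feat)])
        # pairwise scaled distances over jointly observed samples
        Lz = np.where(obs, L, 0.0)
        obs_f = obs.astype(float)
        common = obs_f @ obs_f.T
        sq = Lz**2
        cross = Lz @ Lz.T
        ssd = (sq @ obs_f.T) + (obs_f @ sq.T) - 2.0 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = ssd / common * n_samp
            # pairwise mean log offsets over jointly observed samples
            A = Lz @ obs_f.T  # A[i,g] = sum of L_i over common(i,g)
            delta = (A - A.T) / common
        dist[common == 0] = np.inf
        np.fill_diagonal(dist, np.inf)

        out = X.copy()
        for i, s in zip(*np.where(~obs)):
            cand = np.flatnonzero(obs[:, s] & np.isfinite(dist[i]))
            if cand.size == 0:
                log_val = means[i]
            else:
                order = cand[np.argsort(dist[i, cand], kind="stable")]
                nb = order[: self.k]
                log_val = (L[nb, s] + delta[i, nb]).mean()
            out[i, s] = np.exp(log_val)
        result = FeatureTable(
            pd.DataFrame(out, index=table.intensities.index,
                         columns=table.intensities.columns),
            table.samples, table.features,
        )
        if report is not None:
            report.add_stage("knn_imputation", table.n_features,
                             result.n_features)
            report.add_param("knn_k", self.k)
        return result

    def fit_transform(self, table, y=None, report=None):
        return self.fit(table).transform(table, report=report)


# ---------------------------------------------------------------- wrappers
def filter_unknowns(table, report=None):
    """Remove all annotation-level-4 features."""
    return UnknownsFilter().fit_transform(table, report=report)


def filter_by_pool_rsd(table, threshold=30.0, report=None):
    """Remove features with pooled-sample RSD above ``threshold`` %."""
    return PoolRSDFilter(threshold).fit_transform(table, report=report)


def filter_by_missingness(table, max_fraction=0.20, report=None):
    """Remove features missing in more than ``max_fraction`` of samples."""
    return MissingnessFilter(max_fraction).fit_transform(table, report=report)


def knn_impute(table, k=10, report=None):
    """Impute remaining missing values by feature-space kNN (see
    :class:`FeatureKNNImputer`)."""
    return FeatureKNNImputer(k).fit_transform(table, report=report)
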