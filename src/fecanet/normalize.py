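"""Internal-standard normalization.

Each endogenous feature is divided, sample by sample, by the spiked
internal standard (IS) it correlates best with.  Because multiplicative
extraction/injection drift is shared between a feature and the IS measured
in the same injection, the ratio cancels it.

Correlation is computed with Pearson's r on log intensities (drift is
multiplicative, hence additive on logs), restricted to samples where both
the feature and the candidate IS are observed, and candidates are limited
to the feature's own platform.  Pool and study samples are used jointly to
maximize the number of complete pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InsufficientDataError
from .io import FeatureTable, RunReport

__all__ = [
    "InternalStandardNormalizer",
    "select_internal_standard",
    "normalize_to_is",
]

MIN_PAIRS = 3


def _log_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r of log(x), log(y) over jointly observed entries."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return np.nan, n
    lx, ly = np.log(x[ok]), np.log(y[ok])
    sx, sy = lx.std(), ly.std()
    if sx == 0 or sy == 0:
        return 0.0, n
    return float(np.corrcoef(lx, ly)[0, 1]), n


class InternalStandardNormalizer(BaseEstimator):
    """Learn a feature→IS mapping, then divide each feature by its IS.

    Attributes (after :meth:`fit`)
    ------------------------------
    mapping_ : pandas.DataFrame
        Columns ``feature_id``, ``selected_is``, ``r``, ``n_pairs``; one
        row per non-IS feature.
    """

    def __init__(self, min_pairs: int = MIN_PAIRS):
        self.min_pairs = min_pairs

    def fit(self, table: FeatureTable, y=None) -> "InternalStandardNormalizer":
        feats = table.features
        is_mask = feats["is_internal_standard"].astype(bool)
        mat = table.intensities.to_numpy()
        rows = []
        for pf in feats["platform"].unique():
            pf_is = feats.index[is_mask & (feats["platform"] == pf)]
            if len(pf_is) == 0:
                raise ConfigurationError(
                    f"platform {pf!r} has no internal standard"
                )
            targets = feats.index[~is_mask & (feats["platform"] == pf)]
            # candidates in lexicographic id order so ties resolve stably
            cand = sorted(pf_is, key=lambda i: feats.loc[i, "feature_id"])
            for t in targets:
                best = None
                for c in cand:
                    r, n = _log_pearson(mat[t], mat[c])
                    if n < self.min_pairs:
                        continue
                    if best is None or r > best[1] + 1e-15:
                        best = (feats.loc[c, "feature_id"], r, n)
                if best is None:
                    raise InsufficientDataError(
                        f"feature {feats.loc[t, 'feature_id']!r} has no IS "
                        f"candidate with >= {self.min_pairs} complete pairs"
                    )
                rows.append((feats.loc[t, "feature_id"], *best))
        self.mapping_ = pd.DataFrame(
            rows, columns=["feature_id", "selected_is", "r", "n_pairs"]
        )
        return self

    def transform(
        self, table: FeatureTable, report: RunReport | None = None
    ) -> FeatureTable:
        m = self.mapping_.set_index("feature_id")["selected_is"]
        keep = table.features[~table.features["is_internal_standard"]]
        out = table.intensities.loc[keep["feature_id"]].copy()
        for fid in out.index:
            out.loc[fid] = out.loc[fid] / table.intensities.loc[m[fid]]
        if report is not None:
            # internal standards are reagents, not features under study, so
            # stage counts track endogenous features only
            report.add_stage("is_normalization", len(keep), len(out))
            report.add_param(
                "is_mapping", dict(zip(self.mapping_["feature_id"],
                                       self.mapping_["selected_is"]))
            )
        return FeatureTable(out, table.samples, keep)

    def fit_transform(
        self, table: FeatureTable, y=None, report: RunReport | None = None
    ) -> FeatureTable:
        return self.fit(table).transform(table, report=report)


def select_internal_standard(table: FeatureTable, feature_id: str) -> str:
    """Id of the same-platform IS most correlated with ``feature_id``."""
    norm = InternalStandardNormalizer().fit(table)
    m = norm.mapping_.set_index("feature_id")
    if feature_id not in m.index:
        raise KeyError(feature_id)
    return str(m.loc[feature_id, "selected_is"])


def normalize_to_is(
    table: FeatureTable, report: RunReport | None = None
) -> FeatureTable:
    """Normalize every feature by its most-correlated internal standard.

    IS features are dropped from the output; samples where the selected IS
    is missing become missing for the mapped features.
    """
    return InternalStandardNormalizer().fit_transform(table, report=report)
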