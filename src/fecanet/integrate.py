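"""Cross-platform category integration.

Auto-scaled feature values are averaged over each participant's drill
replicates and then over the features of each compound class, giving one
individuals × categories summary per platform; the two summaries are
concatenated and each row standardized for heatmap display of relative
category abundances across individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .io import FeatureTable, ReconciliationError
from .network import autoscale

__all__ = [
    "average_over_replicates",
    "average_over_categories",
    "combine_and_rowscale",
    "integration_matrix",
]


def average_over_replicates(table: FeatureTable) -> pd.DataFrame:
    """Individuals × features matrix of drill-replicate means.

    Missing values are ignored in the mean (on imputed tables this is a
    plain mean).
    """
    if table.n_features == 0:
        raise ValueError("empty feature set")
    study = table.study_sample_ids()
    part = table.samples.set_index("sample_id").loc[study, "participant_id"]
    vals = table.intensities[study].T
    vals.index = part.to_numpy()
    return vals.groupby(level=0, sort=True).mean()


def average_over_categories(
    matrix: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Average feature columns by compound class.

    Column order of the result: platform, then class name.
    """
    cls = features.set_index("feature_id")[["platform", "compound_class"]]
    cols = {}
    keys = cls.loc[list(matrix.columns)]
    for (pf, cc), grp in keys.groupby(
        ["platform", "compound_class"], sort=True
    ):
        cols[(pf, cc)] = matrix[list(grp.index)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = [f"{pf}:{cc}" for pf, cc in out.columns]
    return out


def combine_and_rowscale(
    polar_summary: pd.DataFrame, lipid_summary: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate platform summaries and standardize each row to mean 0,
    SD 1 (n−1)."""
    if set(polar_summary.index) != set(lipid_summary.index):
        only_p = sorted(set(polar_summary.index) - set(lipid_summary.index))
        only_l = sorted(set(lipid_summary.index) - set(polar_summary.index))
        raise ReconciliationError(
            f"individual sets differ: only polar {only_p}, only lipid {only_l}"
        )
    combined = pd.concat(
        [polar_summary, lipid_summary.loc[polar_summary.index]], axis=1
    )
    if combined.shape[1] < 2:
        raise DegenerateDataError(
            "row scaling needs >= 2 categories (SD over one value)"
        )
    vals = combined.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = combined.index[np.flatnonzero(sd == 0)[0]]
        raise DegenerateDataError(f"constant row for individual {bad!r}")
    scaled = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(scaled, index=combined.index,
                        columns=combined.columns)


def integration_matrix(
    table: FeatureTable, out_path: str | None = None
) -> pd.DataFrame:
    """Full integration stage on a QC'd, imputed table.

    log → autoscale features → average over drill replicates → average
    over compound classes per platform → combine platforms → row-scale.
    When ``out_path`` is given, also writes the tidy long-format TSV
    (individual, category, value) behind the heatmap.
    """
    study = table.study_sample_ids()
    L = np.log(table.intensities[study].to_numpy(dtype=float))
    scaled = autoscale(L.T)  # samples × features
    ind_by_feat = pd.DataFrame(
        scaled, index=study, columns=table.feature_ids
    )
    part = table.samples.set_index("sample_id").loc[study, "participant_id"]
    ind_by_feat.index = part.to_numpy()
    reps = ind_by_feat.groupby(level=0, sort=True).mean()
    is_polar = table.features["platform"] == "polar"
    polar_ids = list(table.features.loc[is_polar, "feature_id"])
    lipid_ids = list(table.features.loc[~is_polar, "feature_id"])
    polar = average_over_categories(reps[polar_ids], table.features)
    lipid = average_over_categories(reps[lipid_ids], table.features)
    out = combine_and_rowscale(polar, lipid)
    if out_path is not None:
        tidy = out.reset_index(names="individual").melt(
            id_vars="individual", var_name="category", value_name="value"
        )
        tidy.to_csv(out_path, sep="\t", index=False, lineterminator="\n")
    return out
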