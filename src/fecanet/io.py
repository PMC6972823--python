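"""Peak-table data model and TSV I/O.

The exchange format is three tab-separated UTF-8 files:

* peak table — ``feature_id<TAB>sample1<TAB>...`` with one row per feature,
  intensities in arbitrary units, missing cells empty or ``NA``;
* sample metadata — ``sample_id, participant_id, drill_area, sample_type``
  with ``sample_type`` in ``{study, pool}``;
* feature metadata — ``feature_id, name, platform, compound_class,
  annotation_level, is_internal_standard`` with ``platform`` in
  ``{polar, lipid}`` and annotation levels 1 (authentic standard) to 4
  (unknown).

Intensities are kept on the raw linear scale; operations that need logs
transform internally and never store the transformed values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "RunReport",
    "FormatError",
    "ReconciliationError",
    "read_feature_table",
    "write_feature_table",
    "merge_platforms",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}
_SAMPLE_COLS = ["sample_id", "participant_id", "drill_area", "sample_type"]
_FEATURE_COLS = [
    "feature_id",
    "name",
    "platform",
    "compound_class",
    "annotation_level",
    "is_internal_standard",
]


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad enum, negative intensity)."""


class ReconciliationError(ValueError):
    """Peak table and metadata disagree about which samples/features exist."""


@dataclass
class RunReport:
    """Provenance of a pipeline run: stage feature counts, parameters, seeds.

    ``stage_counts`` is an ordered list of ``(stage, n_in, n_out)``; the
    features-out of stage *k* must equal features-in of stage *k + 1*.
    """

    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)
    parameters: list[tuple[str, object]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        if self.stage_counts and self.stage_counts[-1][2] != n_in:
            raise ValueError(
                f"stage {name!r}: features-in {n_in} does not match previous "
                f"stage's features-out {self.stage_counts[-1][2]}"
            )
        self.stage_counts.append((name, int(n_in), int(n_out)))

    def add_param(self, name: str, value: object) -> None:
        self.parameters.append((name, value))

    def to_dict(self) -> dict:
        return {
            "stage_counts": [
                {"stage": s, "features_in": a, "features_out": b}
                for s, a, b in self.stage_counts
            ],
            "parameters": {k: v for k, v in self.parameters},
            "seeds": list(self.seeds),
        }


class FeatureTable:
    """Intensity matrix (features × samples) with sample/feature metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Non-negative intensities, ``NaN`` for missing; index = feature ids,
        columns = sample ids.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``participant_id``,
        ``drill_area``, ``sample_type``; row order defines column order of
        ``intensities``.
    features : pandas.DataFrame
        One row per feature with columns ``feature_id``, ``name``,
        ``platform``, ``compound_class``, ``annotation_level``,
        ``is_internal_standard``; row order defines row order of
        ``intensities``.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        samples: pd.DataFrame,
        features: pd.DataFrame,
    ):
        self.intensities = intensities.astype(float)
        self.samples = samples.reset_index(drop=True)
        self.features = features.reset_index(drop=True)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        sids = self.samples["sample_id"].astype(str)
        fids = self.features["feature_id"].astype(str)
        for ids, what in ((sids, "sample"), (fids, "feature")):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise FormatError(f"duplicate {what} id: {dup.iloc[0]!r}")
        if list(self.intensities.columns) != list(sids):
            missing = set(sids) - set(self.intensities.columns)
            extra = set(self.intensities.columns) - set(sids)
            raise ReconciliationError(
                f"peak-table samples and sample metadata disagree: "
                f"missing from peak table {sorted(missing)}, "
                f"missing from metadata {sorted(extra)}"
            )
        if list(self.intensities.index) != list(fids):
            missing = set(fids) - set(self.intensities.index)
            extra = set(self.intensities.index) - set(fids)
            raise ReconciliationError(
                f"peak-table features and feature metadata disagree: "
                f"missing from peak table {sorted(missing)}, "
                f"missing from metadata {sorted(extra)}"
            )
        vals = self.intensities.to_numpy()
        bad = np.where(np.isfinite(vals) & (vals < 0))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise FormatError(
                f"negative intensity at feature "
                f"{self.intensities.index[i]!r}, sample "
                f"{self.intensities.columns[j]!r}"
            )
        if np.isinf(vals).any():
            raise FormatError("non-finite intensity (inf) in peak table")
        bad_level = ~self.features["annotation_level"].isin([1, 2, 3, 4])
        if bad_level.any():
            raise FormatError(
                f"annotation_level outside 1-4 for feature "
                f"{self.features.loc[bad_level, 'feature_id'].iloc[0]!r}"
            )
        is_mask = self.features["is_internal_standard"].astype(bool)
        if (self.features.loc[is_mask, "annotation_level"] != 1).any():
            raise FormatError("internal standards must be annotation level 1")
        bad_pf = ~self.features["platform"].isin(["polar", "lipid"])
        if bad_pf.any():
            raise FormatError(
                f"unknown platform "
                f"{self.features.loc[bad_pf, 'platform'].iloc[0]!r}"
            )
        st = self.samples["sample_type"]
        if (~st.isin(["study", "pool"])).any():
            raise FormatError("sample_type must be 'study' or 'pool'")
        study = st == "study"
        pid = self.samples["participant_id"]
        area = self.samples["drill_area"]
        if (study & (pid.isna() | (pid.astype(str) == ""))).any():
            raise FormatError("study sample without participant_id")
        if (study & area.isna()).any():
            raise FormatError("study sample without drill_area")
        if (~study & pid.notna() & (pid.astype(str) != "")).any():
            raise FormatError("pool sample with participant_id set")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features["feature_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def pool_sample_ids(self) -> list[str]:
        m = self.samples["sample_type"] == "pool"
        return list(self.samples.loc[m, "sample_id"])

    def study_sample_ids(self) -> list[str]:
        m = self.samples["sample_type"] == "study"
        return list(self.samples.loc[m, "sample_id"])

    def subset_features(self, feature_ids) -> "FeatureTable":
        keep = [fid for fid in self.feature_ids if fid in set(feature_ids)]
        feats = self.features.set_index("feature_id").loc[keep].reset_index()
        return FeatureTable(self.intensities.loc[keep], self.samples, feats)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        keep = [sid for sid in self.sample_ids if sid in set(sample_ids)]
        samp = self.samples.set_index("sample_id").loc[keep].reset_index()
        return FeatureTable(self.intensities[keep], samp, self.features)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.features.copy()
        )

    def equals(self, other: "FeatureTable") -> bool:
        a, b = self.intensities, other.intensities
        same_vals = a.shape == b.shape and bool(
            ((a.to_numpy() == b.to_numpy())
             | (np.isnan(a.to_numpy()) & np.isnan(b.to_numpy()))).all()
        )
        return (
            same_vals
            and list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FeatureTable({self.n_features} features × "
            f"{self.n_samples} samples)"
        )


# ----------------------------------------------------------------------
def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )


def read_feature_table(
    peak_path: str, sample_meta_path: str, feature_meta_path: str
) -> FeatureTable:
    """Read and validate the three-TSV peak-table format.

    Missing intensities may be encoded as empty cells, ``NA`` or ``NaN``.
    Unknown metadata columns are preserved but ignored.
    """
    peak = _read_tsv(peak_path)
    if peak.columns[0] != "feature_id":
        peak = peak.rename(columns={peak.columns[0]: "feature_id"})
    samples = _read_tsv(sample_meta_path)
    features = _read_tsv(feature_meta_path)
    for col in _SAMPLE_COLS:
        if col not in samples.columns:
            raise FormatError(f"sample metadata lacks column {col!r}")
    for col in _FEATURE_COLS:
        if col not in features.columns:
            raise FormatError(f"feature metadata lacks column {col!r}")

    def parse_cell(x: str) -> float:
        if x in _MISSING_TOKENS:
            return np.nan
        return float(x)

    mat = peak.set_index("feature_id").map(parse_cell).astype(float)
    samples = samples.copy()
    samples["participant_id"] = samples["participant_id"].replace(
        {t: np.nan for t in _MISSING_TOKENS}
    )
    samples["drill_area"] = pd.to_numeric(
        samples["drill_area"].replace({t: np.nan for t in _MISSING_TOKENS})
    ).astype("Int64")
    features = features.copy()
    features["annotation_level"] = features["annotation_level"].astype(int)
    features["is_internal_standard"] = (
        features["is_internal_standard"]
        .str.lower()
        .map({"true": True, "false": False, "1": True, "0": False})
        .astype(bool)
    )
    # align peak-table column/row order to the metadata order
    sids = list(samples["sample_id"])
    fids = list(features["feature_id"])
    if set(mat.columns) != set(sids):
        only_peak = sorted(set(mat.columns) - set(sids))
        only_meta = sorted(set(sids) - set(mat.columns))
        raise ReconciliationError(
            f"sample sets differ: only in peak table {only_peak}, "
            f"only in metadata {only_meta}"
        )
    if set(mat.index) != set(fids):
        only_peak = sorted(set(mat.index) - set(fids))
        only_meta = sorted(set(fids) - set(mat.index))
        raise ReconciliationError(
            f"feature sets differ: only in peak table {only_peak}, "
            f"only in metadata {only_meta}"
        )
    mat = mat.loc[fids, sids]
    return FeatureTable(mat, samples, features)


def write_feature_table(table: FeatureTable, out_dir: str) -> tuple[str, str, str]:
    """Write a table as peak/sample-meta/feature-meta TSVs.

    Round-trips exactly through :func:`read_feature_table`: missing values
    are written as ``NA`` and intensities with full ``repr`` precision.
    """
    os.makedirs(out_dir, exist_ok=True)
    peak_path = os.path.join(out_dir, "peak_table.tsv")
    sample_path = os.path.join(out_dir, "sample_metadata.tsv")
    feature_path = os.path.join(out_dir, "feature_metadata.tsv")
    mat = table.intensities.map(lambda v: "NA" if pd.isna(v) else repr(v))
    mat.index.name = "feature_id"
    mat.to_csv(peak_path, sep="\t", lineterminator="\n")
    samples = table.samples.copy()
    samples["participant_id"] = samples["participant_id"].fillna("NA")
    samples["drill_area"] = samples["drill_area"].astype("Int64").astype(str)
    samples["drill_area"] = samples["drill_area"].replace({"<NA>": "NA"})
    samples.to_csv(sample_path, sep="\t", index=False, lineterminator="\n")
    features = table.features.copy()
    features["is_internal_standard"] = features["is_internal_standard"].map(
        {True: "true", False: "false"}
    )
    features.to_csv(feature_path, sep="\t", index=False, lineterminator="\n")
    return peak_path, sample_path, feature_path


def merge_platforms(polar: FeatureTable, lipid: FeatureTable) -> FeatureTable:
    """Row-concatenate two platform tables over an identical sample set.

    Sample order is taken from the polar table.  Feature ids are prefixed
    with their platform only if a collision would otherwise occur.
    """
    a, b = set(polar.sample_ids), set(lipid.sample_ids)
    if a != b:
        raise ReconciliationError(
            f"sample sets differ: only polar {sorted(a - b)}, "
            f"only lipid {sorted(b - a)}"
        )
    lipid_mat = lipid.intensities[polar.sample_ids]
    collide = set(polar.feature_ids) & set(lipid.feature_ids)
    pol_feats, lip_feats = polar.features.copy(), lipid.features.copy()
    pol_mat = polar.intensities.copy()
    lip_mat = lipid_mat.copy()
    if collide:
        pol_map = {f: f"polar:{f}" if f in collide else f
                   for f in polar.feature_ids}
        lip_map = {f: f"lipid:{f}" if f in collide else f
                   for f in lipid.feature_ids}
        pol_feats["feature_id"] = pol_feats["feature_id"].map(pol_map)
        lip_feats["feature_id"] = lip_feats["feature_id"].map(lip_map)
        pol_mat.index = pol_feats["feature_id"].to_numpy()
        lip_mat.index = lip_feats["feature_id"].to_numpy()
    return FeatureTable(
        pd.concat([pol_mat, lip_mat], axis=0),
        polar.samples,
        pd.concat([pol_feats, lip_feats], axis=0),
    )
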