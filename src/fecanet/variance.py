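"""Three-level CV decomposition and feature-wise moderated F-tests.

Each feature's variation is summarized by three relative standard
deviations:

* **technical CV** — RSD across pooled-QC injections (pure measurement
  repeatability, since every pool injects the same material);
* **drill-area CV** — mean, over participants, of the RSD across that
  participant's drill-area replicates (specimen heterogeneity);
* **participant CV** — RSD across participant means (between-person
  variation).

Averaging within-participant RSDs, rather than pooling all drills, keeps
participant-level variance out of the heterogeneity number.

Whether individuals differ per feature is tested with a one-way ANOVA on
log intensities (participant as the factor), optionally with
empirical-Bayes moderation of the residual variance: each feature's
within-group mean square is shrunk toward a common prior estimated by
moment-matching of the log variances across features, and the moderated F
gains the prior degrees of freedom — the standard moderated F-statistic
for small-n omics designs.  P-values are corrected with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .io import FeatureTable
from .qc import _rsd_rows

__all__ = [
    "technical_cv",
    "area_cv",
    "participant_cv",
    "feature_f_test",
    "bh_adjust",
    "variance_profile",
    "VarianceDecomposer",
]


# ------------------------------------------------------------------ CVs
def _technical_cv_rows(table: FeatureTable) -> np.ndarray:
    pools = table.pool_sample_ids()
    if len(pools) < 2:
        raise InsufficientDataError("technical CV needs >= 2 pool samples")
    return _rsd_rows(table.intensities[pools].to_numpy())


def _area_cv_rows(table: FeatureTable) -> np.ndarray:
    samples = table.samples
    study = samples[samples["sample_type"] == "study"]
    per_part = []
    for _, grp in study.groupby("participant_id", sort=True):
        mat = table.intensities[list(grp["sample_id"])].to_numpy()
        per_part.append(_rsd_rows(mat))
    stacked = np.vstack(per_part)  # participants × features
    if np.isnan(stacked).all(axis=0).any() and len(per_part) == 0:
        raise InsufficientDataError("no participant with >= 2 drill values")
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def _participant_cv_rows(table: FeatureTable) -> np.ndarray:
    samples = table.samples
    study = samples[samples["sample_type"] == "study"]
    means = []
    for _, grp in study.groupby("participant_id", sort=True):
        mat = table.intensities[list(grp["sample_id"])].to_numpy()
        with np.errstate(invalid="ignore"):
            means.append(np.nanmean(mat, axis=1))
    return _rsd_rows(np.vstack(means).T)


def _one_feature(fn, table: FeatureTable, feature_id: str) -> float:
    sub = table.subset_features([feature_id])
    val = fn(sub)[0]
    if np.isnan(val):
        raise InsufficientDataError(
            f"cannot compute CV for feature {feature_id!r}"
        )
    return float(val)


def technical_cv(table: FeatureTable, feature_id: str) -> float:
    """RSD (%) of the feature across pooled-QC injections."""
    return _one_feature(_technical_cv_rows, table, feature_id)


def area_cv(table: FeatureTable, feature_id: str) -> float:
    """Mean within-participant RSD (%) across drill-area replicates."""
    return _one_feature(_area_cv_rows, table, feature_id)


def participant_cv(table: FeatureTable, feature_id: str) -> float:
    """RSD (%) across participant means (drill replicates averaged)."""
    return _one_feature(_participant_cv_rows, table, feature_id)


# ------------------------------------------------------------ F-testing
def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to sample variances.

    Smyth-style: the log sample variances of null-varying features follow
    ``log s0^2 + log F(df, d0)``; matching the mean and variance of
    ``log s2`` via digamma/trigamma gives the prior df and scale.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0_2 = float(np.exp(
        emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ))
    return d0, s0_2


def feature_f_test(
    table: FeatureTable, moderation: str = "empirical_bayes"
) -> pd.DataFrame:
    """Per-feature one-way ANOVA with participant as the factor.

    Computed on log intensities over study samples only (the factor is
    undefined for pools).  Returns a DataFrame indexed by feature id with
    columns ``F``, ``p``, ``df1``, ``df2``.  Features constant across all
    samples get ``F = 0, p = 1``.

    With ``moderation="empirical_bayes"`` the within-group mean square is
    shrunk toward an estimated common prior (d0, s0^2):
    ``s2_post = (d0*s0^2 + d_g*s2) / (d0 + d_g)`` and the moderated F has
    ``(g - 1, d0 + d_g)`` degrees of freedom.
    """
    if moderation not in ("none", "empirical_bayes"):
        raise ValueError("moderation must be 'none' or 'empirical_bayes'")
    study_ids = table.study_sample_ids()
    X = table.intensities[study_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.log(X)
    part = table.samples.set_index("sample_id").loc[
        study_ids, "participant_id"
    ]
    codes, groups = pd.factorize(part, sort=True)
    if len(groups) < 2:
        raise InsufficientDataError("F-test needs >= 2 participants")
    obs = np.isfinite(L)
    nf = L.shape[0]
    g = len(groups)
    grp_sum = np.zeros((nf, g))
    grp_n = np.zeros((nf, g))
    for j, c in enumerate(codes):
        col = L[:, j]
        ok = obs[:, j]
        grp_sum[ok, c] += col[ok]
        grp_n[ok, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        grp_mean = grp_sum / grp_n
    n_tot = grp_n.sum(axis=1)
    grand = np.nansum(np.where(obs, L, 0.0), axis=1) / n_tot
    g_eff = (grp_n > 0).sum(axis=1)
    ss_between = np.nansum(
        grp_n * (grp_mean - grand[:, None]) ** 2, axis=1
    )
    tot_ss = np.nansum(np.where(obs, (L - grand[:, None]) ** 2, 0.0), axis=1)
    ss_within = tot_ss - ss_between
    df1 = g_eff - 1.0
    df2 = n_tot - g_eff
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_between = ss_between / df1
        s2 = ss_within / df2

    constant = tot_ss <= 1e-300
    if moderation == "empirical_bayes":
        # assume a common residual df (true for balanced complete designs)
        df_common = float(np.median(df2[df2 > 0]))
        d0, s0_2 = _fit_f_dist(s2[~constant & (df2 > 0)], df_common)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            # effectively infinite prior df; keep finite for scipy's F
            df2_post = np.full_like(df2, 1e9)
        else:
            s2_post = (d0 * s0_2 + df2 * s2) / (d0 + df2)
            df2_post = df2 + d0
    else:
        s2_post = s2
        df2_post = df2

    with np.errstate(invalid="ignore", divide="ignore"):
        F = ms_between / s2_post
    p = np.where(
        np.isfinite(F),
        stats.f.sf(F, df1, df2_post),
        0.0,
    )
    F = np.where(constant, 0.0, F)
    p = np.where(constant, 1.0, p)
    return pd.DataFrame(
        {"F": F, "p": p, "df1": df1, "df2": df2_post},
        index=table.feature_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- profiles
class VarianceDecomposer(BaseEstimator):
    """Assemble per-feature variance profiles for a QC'd table.

    After :meth:`fit`, ``profiles_`` holds one row per feature with the
    three CVs, the (moderated) F statistic, p and BH-adjusted q — the
    tidy data behind the per-platform bubble plots.
    """

    def __init__(self, moderation: str = "empirical_bayes"):
        self.moderation = moderation

    def fit(self, table: FeatureTable, y=None):
        ft = feature_f_test(table, moderation=self.moderation)
        prof = pd.DataFrame(
            {
                "feature_id": table.feature_ids,
                "name": table.features["name"].to_numpy(),
                "compound_class": table.features["compound_class"].to_numpy(),
                "platform": table.features["platform"].to_numpy(),
                "cv_technical": _technical_cv_rows(table),
                "cv_area": _area_cv_rows(table),
                "cv_participant": _participant_cv_rows(table),
                "F": ft["F"].to_numpy(),
                "p": ft["p"].to_numpy(),
            }
        )
        prof["q"] = bh_adjust(prof["p"].to_numpy())
        self.profiles_ = prof
        return self


def variance_profile(
    table: FeatureTable,
    moderation: str = "empirical_bayes",
    out_dir: str | None = None,
) -> pd.DataFrame:
    """Per-feature CV decomposition + moderated F-test results.

    When ``out_dir`` is given, writes one tidy TSV per platform
    (``variance_polar.tsv``, ``variance_lipid.tsv``) with the columns
    behind the bubble plots.
    """
    prof = VarianceDecomposer(moderation=moderation).fit(table).profiles_
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for pf in ("polar", "lipid"):
            sub = prof[prof["platform"] == pf]
            sub.to_csv(
                os.path.join(out_dir, f"variance_{pf}.tsv"),
                sep="\t", index=False, lineterminator="\n",
            )
    return prof


def plot_bubble(profiles: pd.DataFrame, path: str) -> None:
    """Scatter of participant CV vs drill-area CV, colored by class,
    with 30 % guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, sub in profiles.groupby("compound_class"):
        ax.scatter(sub["cv_area"], sub["cv_participant"],
                   s=20, label=cls, alpha=0.7)
    ax.axvline(30, ls="--", c="grey")
    ax.axhline(30, ls="--", c="grey")
    ax.set_xlabel("drill-area CV (%)")
    ax.set_ylabel("participant CV (%)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
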