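"""Synthetic fecal-metabolome study generator.

Emulates the study design the analysis pipeline targets: 10 participants,
each cryogenically drilled in 4 areas, plus pooled-QC injections; two
analytical platforms (polar metabolites, lipids) with spiked internal
standards; a hierarchical multiplicative error model with technical,
drill-area and participant variance levels; below-LOD censoring; and a
planted sparse Gaussian graphical model on a subset of features so that
network recovery can be scored against ground truth.

Generative model (log scale), for feature *f*, participant *i*, area *a*::

    log x = mu_f + s_j + b_{f,i} + d_{f,i,a} + eps

* ``mu_f`` — base abundance, uniform on [log 1e4, log 1e6];
* ``s_j`` — per-sample, per-platform extraction/drift factor,
  N(0, sigma_extraction^2), shared by every feature of the platform in
  that injection (this is what internal-standard normalization removes);
* ``b_{f,i}`` — participant effect, N(0, sigma_P^2); for the
  ``network_size`` selected features the participant-effect vector is
  multivariate normal with covariance inverse(true_precision), rescaled so
  each marginal variance equals sigma_P^2;
* ``d_{f,i,a}`` — drill-area effect, N(0, sigma_A^2);
* ``eps`` — technical noise, N(0, sigma_T^2).

Pooled-QC injections measure the grand mean of the study material
(mean over all aliquots of b + d) plus a fresh extraction factor and fresh
technical noise, so their replicate RSD estimates technical variation by
construction.  Internal standards carry no biological components (constant
true amount) and are simulated with half the technical log-SD of
endogenous features, reflecting spiked compounds at optimal abundance.
Level-4 unknowns carry no biological signal and doubled technical noise.

Log-scale SDs are derived from the configured CV percentages through the
log-normal identity ``CV = sqrt(exp(sigma^2) - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "expected_cv",
    "sigma_for_cv",
    "simulate_precision",
    "simulate_study",
]

POLAR_CLASSES = [
    "amino acid",
    "benzene derivative",
    "carboxylic acid",
    "fatty acid derivative",
    "amine",
    "indole derivative",
    "purine derivative",
    "pyrimidine derivative",
]
LIPID_CLASSES = ["Cer", "DG", "TG", "PC", "LPC", "SM", "PG", "PI"]


def expected_cv(sigma: float) -> float:
    """CV (%) of a log-normal variable with log-scale SD ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return 100.0 * np.sqrt(np.expm1(sigma**2))


def sigma_for_cv(cv_percent: float) -> float:
    """Log-scale SD giving a log-normal CV of ``cv_percent`` %."""
    if cv_percent < 0:
        raise ValueError("cv must be non-negative")
    return float(np.sqrt(np.log1p((cv_percent / 100.0) ** 2)))


@dataclass
class SimulationConfig:
    """Study-design and error-model parameters.

    Defaults reproduce the target design: 10 participants × 4 drill areas,
    8 pooled-QC injections, 182 polar + 116 lipid annotated features plus
    2028 level-4 unknowns (2326 features in total), 3 internal standards
    per platform, technical/area/participant CVs of 10/25/60 %.
    """

    n_participants: int = 10
    n_areas: int = 4
    n_pools: int = 8
    n_polar: int = 182
    n_lipid: int = 116
    n_unknowns: int = 2028
    n_is_per_platform: int = 3
    cv_technical: float = 10.0
    cv_area: float = 25.0
    cv_participant: float = 60.0
    sigma_extraction: float = 0.3
    network_size: int = 30
    network_density: float = 0.1
    network_hub_degree: int | None = None
    lod_quantile: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_participants", "n_areas", "n_pools", "n_polar", "n_lipid",
            "n_is_per_platform",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_unknowns < 0:
            raise ValueError("n_unknowns must be >= 0")
        for name in ("cv_technical", "cv_area", "cv_participant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.network_density <= 1:
            raise ValueError("network_density must be in [0, 1]")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.network_size > self.n_polar + self.n_lipid:
            raise ValueError(
                "network_size exceeds the number of annotated features"
            )


@dataclass
class SimulationTruth:
    """Every latent quantity of a simulated study."""

    sigma_technical: float
    sigma_area: float
    sigma_participant: float
    sigma_extraction: float
    is_candidates: dict[str, list[str]]
    network_features: list[str]
    true_precision: np.ndarray
    lod_threshold: dict[str, float]
    censored_positions: list[tuple[str, str]]
    mu: dict[str, float]
    participant_effects: pd.DataFrame
    seed: int
    config: SimulationConfig = field(repr=False, default=None)

    def to_json(self, path: str) -> None:
        payload = {
            "sigma_technical": self.sigma_technical,
            "sigma_area": self.sigma_area,
            "sigma_participant": self.sigma_participant,
            "sigma_extraction": self.sigma_extraction,
            "is_candidates": self.is_candidates,
            "network_features": self.network_features,
            "true_precision": np.asarray(self.true_precision).tolist(),
            "lod_threshold": self.lod_threshold,
            "censored_positions": [list(t) for t in self.censored_positions],
            "seed": self.seed,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_precision(
    p: int,
    density: float,
    seed: int,
    hub: tuple[int, int] | None = None,
) -> np.ndarray:
    """Random sparse symmetric positive-definite precision matrix.

    Off-diagonal support is chosen uniformly at random at the requested
    edge density; nonzero entries are drawn uniformly from ±[0.2, 0.5];
    the diagonal is set to each row's absolute off-diagonal sum plus 0.5
    (diagonal dominance ⇒ positive definite).

    Parameters
    ----------
    hub : (node, degree), optional
        Force ``node`` to have at least ``degree`` neighbours (used to
        plant a known hub for recovery experiments).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(density * len(pairs)))
    chosen = set(
        map(tuple, np.asarray(pairs)[
            rng.choice(len(pairs), size=n_edges, replace=False)
        ])
    ) if n_edges else set()
    if hub is not None:
        node, degree = hub
        neigh = {j for (i, j) in chosen if i == node} | {
            i for (i, j) in chosen if j == node
        }
        candidates = [j for j in range(p) if j != node and j not in neigh]
        extra = rng.choice(
            len(candidates), size=max(0, degree - len(neigh)), replace=False
        )
        for k in extra:
            j = candidates[k]
            chosen.add((min(node, j), max(node, j)))
    K = np.zeros((p, p))
    for (i, j) in sorted(chosen):
        v = rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
        K[i, j] = K[j, i] = v
    np.fill_diagonal(K, np.abs(K).sum(axis=1) + 0.5)
    K = (K + K.T) / 2.0
    assert np.linalg.eigvalsh(K).min() > 0
    return K


def _feature_frame(cfg: SimulationConfig) -> pd.DataFrame:
    """Feature metadata: annotated features, internal standards, unknowns."""
    rows = []
    for k in range(cfg.n_is_per_platform):
        rows.append(("polar_IS%d" % (k + 1), "polar internal standard %d" % (k + 1),
                     "polar", "internal standard", 1, True))
    for k in range(cfg.n_polar):
        rows.append(("P%04d" % (k + 1), "polar_compound_%03d" % (k + 1),
                     "polar", POLAR_CLASSES[k % len(POLAR_CLASSES)],
                     1 + k % 3, False))
    for k in range(cfg.n_is_per_platform):
        rows.append(("lipid_IS%d" % (k + 1), "lipid internal standard %d" % (k + 1),
                     "lipid", "internal standard", 1, True))
    for k in range(cfg.n_lipid):
        rows.append(("L%04d" % (k + 1), "lipid_compound_%03d" % (k + 1),
                     "lipid", LIPID_CLASSES[k % len(LIPID_CLASSES)],
                     1 + k % 3, False))
    # level-4 unknowns, split across platforms pro rata
    n_unk_polar = int(round(
        cfg.n_unknowns * cfg.n_polar / (cfg.n_polar + cfg.n_lipid)
    ))
    for k in range(cfg.n_unknowns):
        platform = "polar" if k < n_unk_polar else "lipid"
        rows.append(("U%04d" % (k + 1), "unknown_%04d" % (k + 1),
                     platform, "unknown", 4, False))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "name", "platform", "compound_class",
                 "annotation_level", "is_internal_standard"],
    )


def _sample_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_participants):
        pid = "V%02d" % (i + 1)
        for a in range(1, cfg.n_areas + 1):
            rows.append(("%s_A%d" % (pid, a), pid, a, "study"))
    for k in range(cfg.n_pools):
        rows.append(("POOL%02d" % (k + 1), np.nan, np.nan, "pool"))
    df = pd.DataFrame(
        rows, columns=["sample_id", "participant_id", "drill_area",
                       "sample_type"]
    )
    df["drill_area"] = df["drill_area"].astype("Int64")
    return df


def simulate_study(
    config: SimulationConfig | None = None, **kwargs
) -> tuple[FeatureTable, SimulationTruth]:
    """Simulate one full study; returns the table and all ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    output.
    """
    cfg = config if config is not None else SimulationConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    features = _feature_frame(cfg)
    samples = _sample_frame(cfg)
    n_feat, n_samp = len(features), len(samples)
    fids = features["feature_id"].to_numpy()
    is_mask = features["is_internal_standard"].to_numpy(bool)
    unk_mask = (features["annotation_level"] == 4).to_numpy()
    annot_mask = ~is_mask & ~unk_mask
    platform = features["platform"].to_numpy()

    study = samples["sample_type"] == "study"
    part_codes = pd.Categorical(
        samples.loc[study, "participant_id"],
        categories=sorted(samples.loc[study, "participant_id"].unique()),
    ).codes
    n_part = cfg.n_participants

    sigma_T = sigma_for_cv(cfg.cv_technical)
    sigma_A = sigma_for_cv(cfg.cv_area)
    sigma_P = sigma_for_cv(cfg.cv_participant)

    mu = rng.uniform(np.log(1e4), np.log(1e6), size=n_feat)

    # participant effects b (features × participants)
    b = np.zeros((n_feat, n_part))
    annot_idx = np.flatnonzero(annot_mask)
    net_idx = np.sort(
        rng.choice(annot_idx, size=cfg.network_size, replace=False)
    )
    K = simulate_precision(
        cfg.network_size, cfg.network_density,
        seed=int(rng.integers(2**31)),
        hub=(0, cfg.network_hub_degree)
        if cfg.network_hub_degree else None,
    )
    cov = np.linalg.inv(K)
    d_scale = sigma_P / np.sqrt(np.diag(cov))
    cov_scaled = cov * np.outer(d_scale, d_scale)
    b[annot_idx] = rng.normal(0.0, sigma_P, size=(len(annot_idx), n_part))
    if sigma_P > 0:
        chol = np.linalg.cholesky(cov_scaled)
        b[net_idx] = chol @ rng.standard_normal((cfg.network_size, n_part))
    else:
        b[net_idx] = 0.0

    # drill-area effects d (features × participants × areas)
    d = np.zeros((n_feat, n_part, cfg.n_areas))
    d[annot_idx] = rng.normal(
        0.0, sigma_A, size=(len(annot_idx), n_part, cfg.n_areas)
    )

    # per-sample extraction factors, one per platform
    s = {
        pf: rng.normal(0.0, cfg.sigma_extraction, size=n_samp)
        for pf in ("polar", "lipid")
    }
    s_mat = np.where(platform[:, None] == "polar",
                     s["polar"][None, :], s["lipid"][None, :])

    eps_sd = np.full(n_feat, sigma_T)
    eps_sd[unk_mask] = 2.0 * sigma_T
    eps_sd[is_mask] = 0.5 * sigma_T
    eps = rng.normal(0.0, 1.0, size=(n_feat, n_samp)) * eps_sd[:, None]

    log_x = np.empty((n_feat, n_samp))
    study_cols = np.flatnonzero(study.to_numpy())
    pool_cols = np.flatnonzero(~study.to_numpy())
    areas = samples.loc[study, "drill_area"].to_numpy(int) - 1
    bio = b[:, part_codes] + d[:, part_codes, areas]  # features × study samples
    log_x[:, study_cols] = mu[:, None] + bio + s_mat[:, study_cols] \
        + eps[:, study_cols]
    pool_bio = (b[:, part_codes] + d[:, part_codes, areas]).mean(axis=1)
    log_x[:, pool_cols] = mu[:, None] + pool_bio[:, None] \
        + s_mat[:, pool_cols] + eps[:, pool_cols]

    x = np.exp(log_x)

    # below-LOD censoring per platform, internal standards exempt
    lod = {}
    censored: list[tuple[str, str]] = []
    for pf in ("polar", "lipid"):
        rows = np.flatnonzero((platform == pf) & ~is_mask)
        thr = float(np.quantile(x[rows], cfg.lod_quantile))
        lod[pf] = thr
        cen = x[rows] < thr
        for ri, ci in zip(*np.where(cen)):
            censored.append((fids[rows[ri]], samples["sample_id"].iloc[ci]))
        x[rows] = np.where(cen, np.nan, x[rows])

    mat = pd.DataFrame(x, index=fids, columns=samples["sample_id"].to_numpy())
    table = FeatureTable(mat, samples, features)

    is_candidates = {
        fid: sorted(fids[(platform == platform[k]) & is_mask])
        for k, fid in enumerate(fids) if not is_mask[k]
    }
    part_ids = sorted(samples.loc[study, "participant_id"].unique())
    truth = SimulationTruth(
        sigma_technical=sigma_T,
        sigma_area=sigma_A,
        sigma_participant=sigma_P,
        sigma_extraction=cfg.sigma_extraction,
        is_candidates=is_candidates,
        network_features=[str(f) for f in fids[net_idx]],
        true_precision=K,
        lod_threshold=lod,
        censored_positions=censored,
        mu={str(f): float(m) for f, m in zip(fids, mu)},
        participant_effects=pd.DataFrame(b, index=fids, columns=part_ids),
        seed=cfg.seed,
        config=cfg,
    )
    return table, truth
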