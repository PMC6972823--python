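"""Sparse partial-correlation network inference.

The pipeline behind the metabolite network: log intensities are averaged
to one value per participant, auto-scaled, and the precision (inverse
covariance) matrix is estimated with an L1-penalized Gaussian likelihood
(graphical lasso).  Zeros of the precision matrix encode conditional
independence; its off-diagonals give partial correlations
``rho_ij = -theta_ij / sqrt(theta_ii * theta_jj)``.

The penalty is selected with a rotation criterion (RIC): the rows of every
column are independently permuted, destroying all cross-feature
dependence while preserving marginals; the maximum absolute off-diagonal
correlation of each such rotation measures the strongest *spurious*
association the sample size can produce, and the penalty is the mean of
this maximum over rotations.  Edges shrunk below that level are therefore
indistinguishable from noise.

The hub is the node with the most connections; remaining nodes are scored
by their Spearman correlation to the hub across individuals (the node
coloring of the network figure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, InsufficientDataError
from .io import FeatureTable

__all__ = [
    "autoscale",
    "graphical_lasso",
    "penalized_objective",
    "kkt_residual",
    "ric_lambda",
    "partial_correlations",
    "build_network",
    "spearman_to_hub",
    "GraphicalLassoRIC",
    "NetworkModel",
    "infer_network",
]


# ----------------------------------------------------------------- scaling
def autoscale(matrix) -> np.ndarray:
    """Column-wise standardization to mean 0, SD 1 (n−1 denominator)."""
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateDataError(f"constant column at index {bad[0]}")
    return (X - mean) / sd


# ------------------------------------------------------------------ glasso
def penalized_objective(theta: np.ndarray, S: np.ndarray,
                        lam: float) -> float:
    """L1-penalized Gaussian log-likelihood
    ``logdet(Theta) - tr(S Theta) - lam * sum_offdiag |theta_ij|``."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(logdet - np.trace(S @ theta) - lam * off)


def kkt_residual(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Worst-case stationarity violation of a glasso solution.

    At the optimum ``Sigma = Theta^{-1}`` satisfies, for i ≠ j,
    ``|Sigma_ij - S_ij| <= lam`` with equality
    ``Sigma_ij - S_ij = lam * sign(theta_ij)`` on the support.
    Returns the largest violation of either condition.
    """
    sigma = np.linalg.inv(theta)
    diff = sigma - S
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    bound = np.maximum(np.abs(diff[off]) - lam, 0.0).max() if p > 1 else 0.0
    support = off & (theta != 0)
    if support.any():
        eq = np.abs(diff[support] - lam * np.sign(theta[support])).max()
    else:
        eq = 0.0
    return float(max(bound, eq))


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> np.ndarray:
    """L1-penalized precision-matrix estimate by block coordinate descent.

    Maximizes ``logdet(Theta) - tr(S Theta) - lam * sum_{i!=j}|theta_ij|``
    (diagonal unpenalized) with the classic algorithm: each column of the
    working covariance is updated by solving an L1-regularized regression
    through coordinate-wise soft-thresholding.

    Parameters
    ----------
    S : (p, p) array
        Symmetric correlation (or covariance) matrix.
    lam : float
        Non-negative penalty.  ``lam >= max |S_ij|`` (i ≠ j) yields a
        diagonal precision matrix.

    Returns
    -------
    theta : (p, p) array
        Symmetric positive-definite precision estimate.  The attribute
        ``graphical_lasso.last_converged`` records convergence of the most
        recent call (a warning is emitted on non-convergence).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    min_eig = float(np.linalg.eigvalsh(S).min())
    if min_eig < 1e-10:
        if lam == 0:
            raise ValueError(
                "lam = 0 requires a non-singular S "
                f"(min eigenvalue {min_eig:.2e})"
            )
        S = S + 1e-8 * np.eye(p)
    if p == 1:
        graphical_lasso.last_converged = True
        return np.array([[1.0 / S[0, 0]]])

    W = S.copy()  # working covariance; diagonal unpenalized => fixed
    B = np.zeros((p, p))  # column regression coefficients (warm-started)
    off = ~np.eye(p, dtype=bool)
    target = tol * max(np.abs(S[off]).mean(), 1e-12)
    converged = False
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.arange(p) != j
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = B[idx, j].copy()
            # coordinate descent for the lasso subproblem; the gradient
            # s12 - W11 @ beta is maintained incrementally so unchanged
            # coordinates cost O(1)
            d = np.diag(W11)
            grad = s12 - W11 @ beta
            for _ in range(200):
                max_delta = 0.0
                for k in range(p - 1):
                    r = grad[k] + d[k] * beta[k]
                    new = np.sign(r) * max(abs(r) - lam, 0.0) / d[k]
                    delta = new - beta[k]
                    if delta != 0.0:
                        beta[k] = new
                        grad -= W11[:, k] * delta
                        if abs(delta) > max_delta:
                            max_delta = abs(delta)
                if max_delta < tol * 1e-2:
                    break
            B[idx, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.abs(W - W_old)[off].mean() < target:
            converged = True
            break
    if not converged:
        warnings.warn(
            "graphical lasso did not converge; returning best iterate",
            RuntimeWarning,
        )
    theta = np.empty((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        beta = B[idx, j]
        theta_jj = 1.0 / (W[j, j] - W[idx, j] @ beta)
        theta[j, j] = theta_jj
        theta[idx, j] = -beta * theta_jj
    theta = (theta + theta.T) / 2.0
    graphical_lasso.last_converged = converged
    return theta


graphical_lasso.last_converged = True


# --------------------------------------------------------------------- RIC
def ric_lambda(data, n_rotations: int = 50, seed: int = 0) -> float:
    """Rotation-criterion penalty: mean over rotations of the maximum
    absolute off-diagonal correlation after independently permuting the
    rows of every column.

    Deterministic given (data, seed): the permutation of column *c* in
    rotation *r* is drawn from a generator seeded by (seed, r, c).
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError("RIC needs >= 3 individuals")
    if p < 2:
        raise InsufficientDataError("RIC needs >= 2 features")
    off = ~np.eye(p, dtype=bool)
    maxima = np.empty(n_rotations)
    for r in range(n_rotations):
        rot = np.empty_like(X)
        for c in range(p):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), r, c])
            )
            rot[:, c] = X[rng.permutation(n), c]
        corr = np.corrcoef(rot, rowvar=False)
        maxima[r] = np.abs(corr[off]).max()
    return float(maxima.mean())


# ----------------------------------------------------- partial correlations
def partial_correlations(theta: np.ndarray) -> np.ndarray:
    """Partial correlations ``-theta_ij / sqrt(theta_ii theta_jj)``,
    zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have positive diagonal")
    denom = np.sqrt(np.outer(d, d))
    rho = -theta / denom
    np.fill_diagonal(rho, 0.0)
    return rho


# ----------------------------------------------------------------- network
@dataclass
class NetworkModel:
    """Fitted partial-correlation network with all audit intermediates."""

    lam: float
    precision: np.ndarray
    partial_corr: np.ndarray
    node_ids: list[str]
    edges: pd.DataFrame  # node_i, node_j, weight, sign
    hub: str
    hub_spearman: dict[str, float] = field(default_factory=dict)
    node_styles: pd.DataFrame | None = None
    converged: bool = True
    correlation: np.ndarray | None = None
    data: pd.DataFrame | None = None

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=self.node_ids, dtype=int)
        for _, e in self.edges.iterrows():
            deg[e["node_i"]] += 1
            deg[e["node_j"]] += 1
        return deg

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        styles = (
            self.node_styles.set_index("feature_id")
            if self.node_styles is not None else None
        )
        for nid in self.node_ids:
            attrs = {"spearman_to_hub": self.hub_spearman.get(nid, 0.0),
                     "is_hub": nid == self.hub}
            if styles is not None and nid in styles.index:
                attrs["platform"] = styles.loc[nid, "platform"]
                attrs["shape"] = styles.loc[nid, "shape"]
            g.add_node(nid, **attrs)
        for _, e in self.edges.iterrows():
            g.add_edge(e["node_i"], e["node_j"],
                       weight=float(e["weight"]), sign=e["sign"])
        return g

    def write(self, out_dir: str) -> None:
        import json
        import os

        import networkx as nx

        os.makedirs(out_dir, exist_ok=True)
        self.edges.to_csv(os.path.join(out_dir, "edges.tsv"), sep="\t",
                          index=False, lineterminator="\n")
        nodes = pd.DataFrame({"feature_id": self.node_ids})
        if self.node_styles is not None:
            nodes = nodes.merge(self.node_styles, on="feature_id",
                                how="left")
        nodes["spearman_to_hub"] = [
            self.hub_spearman.get(n, np.nan) for n in nodes["feature_id"]
        ]
        nodes["is_hub"] = nodes["feature_id"] == self.hub
        nodes.to_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t",
                     index=False, lineterminator="\n")
        nx.write_graphml(self.to_graph(),
                         os.path.join(out_dir, "network.graphml"))
        with open(os.path.join(out_dir, "network_model.json"), "w") as fh:
            json.dump(
                {"lambda": self.lam, "hub": self.hub,
                 "converged": bool(self.converged),
                 "n_nodes": len(self.node_ids),
                 "n_edges": int(len(self.edges))},
                fh, indent=1,
            )


def build_network(
    pcorr: np.ndarray,
    node_meta: pd.DataFrame,
    edge_threshold: float = 1e-8,
) -> NetworkModel:
    """Edge list, hub and node styles from a partial-correlation matrix.

    Edges are all pairs with ``|rho| > edge_threshold`` (the threshold
    separates numerically-zero from shrunk-but-nonzero entries).  The hub
    is the node of maximal degree; ties break by larger sum of absolute
    edge weights, then lexicographic id.  Node shape encodes platform
    (lipid = circle, polar = rectangle).
    """
    pcorr = np.asarray(pcorr, dtype=float)
    node_ids = list(node_meta["feature_id"])
    if len(node_ids) == 0:
        raise ValueError("empty node set")
    p = len(node_ids)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            w = pcorr[i, j]
            if abs(w) > edge_threshold:
                rows.append(
                    (node_ids[i], node_ids[j], float(w),
                     "positive" if w > 0 else "inverse")
                )
    edges = pd.DataFrame(rows,
                         columns=["node_i", "node_j", "weight", "sign"])
    deg = {n: 0 for n in node_ids}
    strength = {n: 0.0 for n in node_ids}
    for _, e in edges.iterrows():
        for n in (e["node_i"], e["node_j"]):
            deg[n] += 1
            strength[n] += abs(e["weight"])
    hub = min(node_ids, key=lambda n: (-deg[n], -strength[n], n))
    styles = pd.DataFrame({
        "feature_id": node_ids,
        "platform": node_meta["platform"].to_numpy(),
        "shape": ["circle" if pf == "lipid" else "rectangle"
                  for pf in node_meta["platform"]],
    })
    return NetworkModel(
        lam=np.nan, precision=None, partial_corr=pcorr, node_ids=node_ids,
        edges=edges, hub=hub, node_styles=styles,
    )


def spearman_to_hub(data: pd.DataFrame, hub: str) -> dict[str, float]:
    """Spearman rank correlation of each feature with the hub across
    individuals (average ranks on ties); the hub maps to 1."""
    if hub not in data.columns:
        raise KeyError(hub)
    h = data[hub].to_numpy(dtype=float)
    if len(h) < 3:
        raise InsufficientDataError("need >= 3 individuals")
    if np.all(h == h[0]):
        raise DegenerateDataError("hub column is constant")
    out = {}
    for col in data.columns:
        if col == hub:
            out[col] = 1.0
        else:
            out[col] = float(
                stats.spearmanr(data[col].to_numpy(dtype=float), h).statistic
            )
    return out


# -------------------------------------------------------------- estimator
class GraphicalLassoRIC(BaseEstimator):
    """Sparse inverse-covariance estimator with rotation-selected penalty.

    A scikit-learn style estimator over an individuals × features matrix:
    ``fit`` auto-scales the columns, selects the penalty with
    :func:`ric_lambda`, runs :func:`graphical_lasso` on the correlation
    matrix and stores the precision and partial-correlation matrices.

    Parameters
    ----------
    n_rotations : int
        Rotations used by the RIC penalty selection.
    random_state : int
        Seed for the rotation permutations.
    tol, max_iter : float, int
        Graphical-lasso convergence controls.

    Attributes
    ----------
    lambda_ : float — selected penalty.
    precision_ : (p, p) ndarray — estimated precision matrix.
    partial_correlations_ : (p, p) ndarray.
    covariance_ : (p, p) ndarray — the input correlation matrix.
    converged_ : bool.
    """

    def __init__(self, n_rotations: int = 50, random_state: int = 0,
                 tol: float = 1e-5, max_iter: int = 500):
        self.n_rotations = n_rotations
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        Z = autoscale(np.asarray(X, dtype=float))
        n = Z.shape[0]
        S = (Z.T @ Z) / (n - 1)
        S = (S + S.T) / 2.0
        self.lambda_ = ric_lambda(Z, n_rotations=self.n_rotations,
                                  seed=self.random_state)
        self.precision_ = graphical_lasso(
            S, self.lambda_, tol=self.tol, max_iter=self.max_iter
        )
        self.converged_ = graphical_lasso.last_converged
        self.covariance_ = S
        self.partial_correlations_ = partial_correlations(self.precision_)
        return self

    def get_precision(self):
        return self.precision_


def infer_network(
    table: FeatureTable,
    level: str = "participant_mean",
    seed: int = 0,
    n_rotations: int = 50,
    edge_threshold: float = 1e-8,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> NetworkModel:
    """Full network pipeline on a QC'd, imputed table.

    log → aggregate to participant means (default) or keep all study
    samples → autoscale → correlation → RIC penalty → graphical lasso →
    partial correlations → edges/hub/styles → Spearman-to-hub coloring.
    """
    if level not in ("participant_mean", "all_study_samples"):
        raise ValueError("level must be participant_mean|all_study_samples")
    study = table.study_sample_ids()
    L = np.log(table.intensities[study].to_numpy(dtype=float))
    if np.isnan(L).any():
        raise ValueError("network inference requires an imputed table")
    part = table.samples.set_index("sample_id").loc[study, "participant_id"]
    if level == "participant_mean":
        df = pd.DataFrame(L.T, index=study, columns=table.feature_ids)
        df["__p"] = part.to_numpy()
        agg = df.groupby("__p", sort=True).mean()
    else:
        agg = pd.DataFrame(L.T, index=study, columns=table.feature_ids)

    est = GraphicalLassoRIC(n_rotations=n_rotations, random_state=seed,
                            tol=tol, max_iter=max_iter).fit(agg.to_numpy())
    model = build_network(est.partial_correlations_, table.features,
                          edge_threshold=edge_threshold)
    model.lam = est.lambda_
    model.precision = est.precision_
    model.converged = est.converged_
    model.correlation = est.covariance_
    model.data = agg
    model.hub_spearman = spearman_to_hub(agg, model.hub)
    return model
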