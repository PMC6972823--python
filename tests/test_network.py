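import numpy as np
import pandas as pd
import pytest

from fecanet import (
    GraphicalLassoRIC,
    autoscale,
    build_network,
    graphical_lasso,
    infer_network,
    partial_correlations,
    ric_lambda,
    spearman_to_hub,
)
from fecanet.errors import DegenerateDataError, InsufficientDataError
from fecanet.network import kkt_residual, penalized_objective

from _oracles import spearman_bruteforce
from conftest import make_table


def random_corr(p, n, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p))
    S = np.corrcoef(A, rowvar=False)
    return (S + S.T) / 2.0


# -------------------------------------------------------------- autoscale
def test_autoscale_definition_and_n2_closed_form():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 9, size=(8, 3))
    Z = autoscale(X)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)
    # two rows: entries are ±1/√2 · √2 = ±0.7071…
    Z2 = autoscale(np.array([[1.0, 5.0], [3.0, 2.0]]))
    assert np.allclose(np.abs(Z2), np.sqrt(0.5))
    # idempotent
    assert np.allclose(autoscale(Z), Z, atol=1e-12)


def test_autoscale_rejects_constant_column():
    with pytest.raises(DegenerateDataError):
        autoscale(np.array([[1.0, 2.0], [1.0, 3.0]]))


# ----------------------------------------------------------------- glasso
def test_large_lambda_gives_diagonal_theta():
    S = random_corr(5, 30, 1)
    lam = np.abs(S[~np.eye(5, dtype=bool)]).max()
    theta = graphical_lasso(S, lam + 1e-6)
    assert np.allclose(theta[~np.eye(5, dtype=bool)], 0.0)


def test_p2_lambda0_partial_corr_equals_pearson():
    for r in (-0.8, -0.3, 0.0, 0.45, 0.9):
        S = np.array([[1.0, r], [r, 1.0]])
        theta = graphical_lasso(S, 0.0, tol=1e-10)
        assert partial_correlations(theta)[0, 1] == pytest.approx(
            r, abs=1e-8)


def test_lambda0_inverts_well_conditioned_S():
    S = random_corr(4, 100, 2)
    theta = graphical_lasso(S, 0.0, tol=1e-9)
    assert np.allclose(theta @ S, np.eye(4), atol=1e-6)


@pytest.mark.parametrize("seed", range(6))
def test_kkt_and_positive_definite(seed):
    p = 3 + seed % 2
    S = random_corr(p, 40, seed)
    for lam in (0.05, 0.1, 0.3):
        theta = graphical_lasso(S, lam, tol=1e-7)
        assert np.linalg.eigvalsh(theta).min() > 0
        assert np.allclose(theta, theta.T)
        assert kkt_residual(theta, S, lam) < 10 * 1e-5


def test_objective_matches_sklearn():
    from sklearn.covariance import graphical_lasso as skgl

    S = random_corr(6, 80, 5)
    for lam in (0.05, 0.2):
        mine = graphical_lasso(S, lam, tol=1e-8)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, ref = skgl(S, alpha=lam, tol=1e-10, max_iter=500)
        assert penalized_objective(mine, S, lam) >= \
            penalized_objective(ref, S, lam) - 1e-6


def test_monotone_sparsity_in_lambda():
    S = random_corr(8, 25, 7)
    grid = [0.01, 0.05, 0.1, 0.2, 0.4, 0.8]
    counts = []
    for lam in grid:
        theta = graphical_lasso(S, lam, tol=1e-7)
        counts.append(int((theta[~np.eye(8, dtype=bool)] != 0).sum()))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_singular_S_refused_at_lambda0():
    A = np.random.default_rng(0).standard_normal((3, 6))  # n < p
    S = np.corrcoef(A, rowvar=False)
    with pytest.raises(ValueError):
        graphical_lasso(S, 0.0)
    theta = graphical_lasso((S + S.T) / 2, 0.3)  # regularized internally
    assert np.linalg.eigvalsh(theta).min() > 0


# -------------------------------------------------------------------- RIC
def test_ric_deterministic_and_positive():
    X = np.random.default_rng(3).standard_normal((30, 6))
    l1 = ric_lambda(X, n_rotations=20, seed=5)
    l2 = ric_lambda(X, n_rotations=20, seed=5)
    assert l1 == l2 > 0


def test_ric_null_calibration():
    """On independent columns the rotation penalty stays small and the
    resulting graph is (near-)empty."""
    rng = np.random.default_rng(11)
    false_counts = []
    for rep in range(10):
        X = rng.standard_normal((1000, 5))
        lam = ric_lambda(X, n_rotations=20, seed=rep)
        assert lam < 0.15
        Z = autoscale(X)
        S = np.corrcoef(Z, rowvar=False)
        theta = graphical_lasso(S, lam)
        false_counts.append(
            int((theta[~np.eye(5, dtype=bool)] != 0).sum()) // 2)
    assert np.mean([c <= 1 for c in false_counts]) >= 0.9


def test_ric_needs_enough_rows():
    with pytest.raises(InsufficientDataError):
        ric_lambda(np.ones((2, 4)), seed=0)


# ------------------------------------------------- partial corr / network
def test_partial_correlation_hand_case():
    theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
    rho = partial_correlations(theta)
    assert rho[0, 1] == pytest.approx(0.5)
    assert rho[0, 0] == rho[1, 1] == 0.0
    assert np.allclose(partial_correlations(np.diag([1.0, 3.0])), 0.0)


def test_partial_correlations_bounded_for_pd():
    K = random_corr(5, 50, 9) + np.eye(5)
    rho = partial_correlations(np.linalg.inv(K))
    off = rho[~np.eye(5, dtype=bool)]
    assert np.all(np.abs(off) < 1.0)
    assert np.allclose(rho, rho.T)


def node_meta(n, platforms=None):
    return pd.DataFrame({
        "feature_id": ["N%d" % i for i in range(n)],
        "platform": platforms or ["polar"] * n,
    })


def test_build_network_planted_degrees():
    rho = np.zeros((4, 4))
    for j in (1, 2, 3):
        rho[0, j] = rho[j, 0] = 0.3
    m = build_network(rho, node_meta(4))
    assert len(m.edges) == 3
    assert m.hub == "N0"
    assert set(m.degree()[["N1", "N2", "N3"]]) == {1}


def test_hub_tie_breaks_lexicographic():
    rho = np.zeros((2, 2))
    rho[0, 1] = rho[1, 0] = -0.4
    m = build_network(rho, node_meta(2))
    assert m.hub == "N0"
    assert m.edges.iloc[0]["sign"] == "inverse"


def test_edge_signs_and_shapes():
    rho = np.array([[0.0, 0.25, -0.3],
                    [0.25, 0.0, 0.0],
                    [-0.3, 0.0, 0.0]])
    m = build_network(rho, node_meta(3, ["polar", "lipid", "polar"]))
    signs = dict(zip(zip(m.edges["node_i"], m.edges["node_j"]),
                     m.edges["sign"]))
    assert signs[("N0", "N1")] == "positive"
    assert signs[("N0", "N2")] == "inverse"
    shapes = m.node_styles.set_index("feature_id")["shape"]
    assert shapes["N1"] == "circle" and shapes["N0"] == "rectangle"


def test_spearman_to_hub_matches_bruteforce_with_ties():
    data = pd.DataFrame({
        "hub": [1.0, 2.0, 2.0, 4.0, 5.0],
        "a": [2.0, 1.0, 3.0, 3.0, 4.0],
        "b": [10.0, 8.0, 8.0, 6.0, 5.0],  # strictly decreasing transform
    })
    got = spearman_to_hub(data, "hub")
    assert got["hub"] == 1.0
    assert got["b"] == pytest.approx(-1.0, abs=1e-12)
    assert got["a"] == pytest.approx(
        spearman_bruteforce(data["a"], data["hub"]), abs=1e-12)
    # monotone transform of the hub has rho = 1
    data["c"] = np.exp(data["hub"])
    assert spearman_to_hub(data, "hub")["c"] == pytest.approx(1.0)


def test_graphical_lasso_ric_estimator_api():
    from sklearn.base import clone

    X = np.random.default_rng(4).standard_normal((40, 5))
    est = GraphicalLassoRIC(n_rotations=10, random_state=1)
    assert clone(est).get_params()["n_rotations"] == 10
    est.fit(X)
    assert est.precision_.shape == (5, 5)
    assert np.linalg.eigvalsh(est.precision_).min() > 0
    assert est.partial_correlations_.shape == (5, 5)
    assert est.lambda_ > 0 and est.converged_


def test_infer_network_deterministic(small_study):
    from fecanet import filter_by_missingness, filter_unknowns, knn_impute

    table, _ = small_study
    t = knn_impute(filter_by_missingness(filter_unknowns(table)))
    m1 = infer_network(t, seed=2, n_rotations=10)
    m2 = infer_network(t, seed=2, n_rotations=10)
    assert m1.lam == m2.lam and m1.hub == m2.hub
    pd.testing.assert_frame_equal(m1.edges, m2.edges)
    assert np.array_equal(m1.precision, m2.precision)
    # audit intermediates retained
    assert m1.correlation is not None and m1.data is not None


def test_network_export_files(tmp_path, small_study):
    import networkx as nx

    from fecanet import filter_by_missingness, filter_unknowns, knn_impute

    table, _ = small_study
    t = knn_impute(filter_by_missingness(filter_unknowns(table)))
    m = infer_network(t, seed=2, n_rotations=10)
    m.write(str(tmp_path))
    g = nx.read_graphml(tmp_path / "network.graphml")
    assert g.number_of_nodes() == len(m.node_ids)
    nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
    assert nodes["is_hub"].sum() == 1
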