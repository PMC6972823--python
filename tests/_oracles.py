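"""Independent reference implementations used only to check the package.

These deliberately share no code with ``fecanet``: the graphical-lasso
oracle maximizes the penalized likelihood by proximal gradient ascent
(ISTA) instead of block coordinate descent; the kNN oracle is an
exhaustive-loop imputer; the BH oracle is a literal step-up recursion.
"""

from __future__ import annotations

import numpy as np


def glasso_objective(theta, S, lam):
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(theta).sum() - np.trace(np.abs(theta))
    return logdet - np.trace(S @ theta) - lam * off


def glasso_bruteforce(S, lam, max_iter=50000, tol=1e-13):
    """Proximal-gradient maximizer of the penalized Gaussian likelihood."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    theta = np.eye(p)

    def smooth(th):
        sign, ld = np.linalg.slogdet(th)
        return np.inf if sign <= 0 else -(ld - np.trace(S @ th))

    def prox(m, t):
        out = np.sign(m) * np.maximum(np.abs(m) - t * lam, 0.0)
        np.fill_diagonal(out, np.diag(m))
        return out

    f = smooth(theta)
    step = 1.0
    stall = 0
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        while True:
            cand = prox(theta - step * grad, step)
            if np.linalg.eigvalsh(cand).min() > 0:
                f_new = smooth(cand)
                diff = cand - theta
                bound = (
                    f + (grad * diff).sum()
                    + (diff**2).sum() / (2.0 * step) + 1e-14
                )
                if f_new <= bound:
                    break
            step *= 0.5
        change = abs(f - f_new)
        theta, f = cand, f_new
        step = min(step * 1.1, 1.0)
        stall = stall + 1 if change < tol else 0
        if stall >= 10:
            break
    return (theta + theta.T) / 2.0


def knn_impute_bruteforce(X, k, n_samples_scale=None):
    """Exhaustive feature-space kNN imputation on log values.

    X: features × samples array with np.nan for missing (linear scale).
    """
    X = np.asarray(X, dtype=float)
    n_feat, n_samp = X.shape
    scale = n_samp if n_samples_scale is None else n_samples_scale
    with np.errstate(invalid="ignore"):
        L = np.log(X)
    obs = ~np.isnan(X)
    means = [L[i][obs[i]].mean() for i in range(n_feat)]
    out = X.copy()
    for i in range(n_feat):
        for s in range(n_samp):
            if obs[i, s]:
                continue
            cands = []
            for g in range(n_feat):
                if g == i or not obs[g, s]:
                    continue
                common = obs[i] & obs[g]
                if not common.any():
                    continue
                d = ((L[i, common] - L[g, common]) ** 2).mean() * scale
                cands.append((d, g))
            cands.sort()
            chosen = [g for _, g in cands[:k]]
            if not chosen:
                lv = means[i]
            else:
                shifted = []
                for g in chosen:
                    common = obs[i] & obs[g]
                    offset = (L[i, common] - L[g, common]).mean()
                    shifted.append(L[g, s] + offset)
                lv = float(np.mean(shifted))
            out[i, s] = np.exp(lv)
    return out


def bh_stepup(p):
    """Literal Benjamini–Hochberg step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, m * p[idx] / rank)
        q[idx] = prev
    return q


def spearman_bruteforce(x, y):
    """Rank (average ties) then Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
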