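"""Independent reference implementations used only to check the package.

These deliberately re-derive results through different code paths:
textbook NIPALS PLS1 with score accumulation (no coefficient propagation),
a direct SVD for PCA, closed-form paired t, and brute-force least squares.
"""

import math

import numpy as np


def nipals_pls1(x, y, n_factors):
    """Textbook NIPALS PLS1; returns (coefficients, intercept, fitted).

    Prediction is accumulated from scores/loadings directly, with the
    standard closed form b = W (P'W)^-1 q for the coefficient vector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    e = x - x_mean
    f = y - y_mean
    ws, ps, qs = [], [], []
    for _ in range(n_factors):
        w = e.T @ f
        w = w / np.linalg.norm(w)
        t = e @ w
        tt = t @ t
        p = e.T @ t / tt
        q = (f @ t) / tt
        e = e - np.outer(t, p)
        f = f - q * t
        ws.append(w)
        ps.append(p)
        qs.append(q)
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_vec = np.asarray(qs)
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    intercept = y_mean - x_mean @ coef
    fitted = x @ coef + intercept
    return coef, intercept, fitted


def svd_pca(x, n_components):
    """PCA loadings/scores/explained % straight from an SVD."""
    x = np.asarray(x, float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[:n_components].T
    scores = xc @ loadings
    explained = np.cumsum(s[:n_components] ** 2) / np.sum(s ** 2) * 100
    return loadings, scores, explained


def paired_t_pvalue(a, b):
    """Two-sided paired Student t from the textbook formula."""
    from scipy.stats import t as t_dist
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0 if d.mean() == 0 else 0.0
    t_stat = d.mean() / (sd / math.sqrt(n))
    return float(2 * t_dist.sf(abs(t_stat), n - 1))


def ols_line(x, y):
    """Normal-equations fit of y = a + b x."""
    a_mat = np.column_stack([np.ones(len(x)), x])
    (a, b), *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    return a, b


def gap_difference_bruteforce(row, g):
    """Literal loop version of the single gap difference."""
    return np.array([row[j + g] - row[j] for j in range(len(row) - g)])
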