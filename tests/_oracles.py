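"""Independent reference implementations used only to check the package.

Each oracle deliberately uses a different algorithm than the shipped
solver: box-constrained L-BFGS-B for the nonnegative lasso (the
objective is smooth on the nonnegative orthant), row-wise block
coordinate descent with a scalar root-find for the L2,1 model, and
plain loops / exhaustive enumeration for matrix and graph operations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize


def nonneg_lasso_objective(w, D, x, lam):
    return 0.5 * np.sum((x - D @ w) ** 2) + lam * np.sum(w)


def nonneg_lasso_lbfgsb(D, x, lam):
    """min_{w>=0} 1/2||x - Dw||^2 + lam*sum(w) via bounded quasi-Newton."""
    n = D.shape[1]

    def fg(w):
        r = D @ w - x
        return 0.5 * float(r @ r) + lam * float(np.sum(w)), D.T @ r + lam

    res = minimize(
        fg,
        np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * n,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.x


def l21_objective(W, y, Xs, lam):
    yc = y - y.mean()
    loss = sum(0.5 * np.sum((yc - x @ W[:, m]) ** 2) for m, x in enumerate(Xs))
    return loss + lam * np.sum(np.linalg.norm(W, axis=1))


def _row_update(a, c, lam):
    """argmin_v sum_m 1/2 a_m v_m^2 - c_m v_m + lam*||v||_2 (a_m > 0)."""
    cn = np.linalg.norm(c)
    if cn <= lam:
        return np.zeros_like(c)

    def g(mu):
        return 1.0 - np.sum((c / (a * mu + lam)) ** 2)

    hi = cn / a.min()
    mu = brentq(g, 1e-300, hi + 1.0, xtol=1e-15, rtol=1e-15)
    return c * mu / (a * mu + lam)


def l21_block_cd(y, Xs, lam, sweeps=4000, tol=1e-13):
    """Row-wise block coordinate descent for the L2,1 association model."""
    yc = y - y.mean()
    d, m = Xs[0].shape[1], len(Xs)
    W = np.zeros((d, m))
    resid = [yc - x @ W[:, j] for j, x in enumerate(Xs)]
    col_sq = np.array([[float(x[:, jf] @ x[:, jf]) for x in Xs] for jf in range(d)])
    prev = l21_objective(W, y, Xs, lam)
    for _ in range(sweeps):
        for jf in range(d):
            a = col_sq[jf]
            if (a == 0).any():
                live = a > 0
                if not live.any():
                    continue
            c = np.array(
                [
                    float(x[:, jf] @ resid[j]) + a[j] * W[jf, j]
                    for j, x in enumerate(Xs)
                ]
            )
            a_safe = np.where(a > 0, a, 1.0)
            v = _row_update(a_safe, np.where(a > 0, c, 0.0), lam)
            v = np.where(a > 0, v, 0.0)
            delta = v - W[jf]
            if np.any(delta):
                for j, x in enumerate(Xs):
                    resid[j] -= x[:, jf] * delta[j]
                W[jf] = v
        cur = l21_objective(W, y, Xs, lam)
        if prev - cur < tol * max(1.0, abs(prev)):
            break
        prev = cur
    return W


def pearson_matrix_bruteforce(ts):
    """Pairwise Pearson coefficients by the textbook covariance formula."""
    t, r = ts.shape
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            xi, xj = ts[:, i], ts[:, j]
            cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
            out[i, j] = out[j, i] = cov / (xi.std() * xj.std())
    return out


def onnela_cc_bruteforce(w):
    """Weighted clustering coefficients by explicit triangle enumeration."""
    r = w.shape[0]
    w = np.abs(np.asarray(w, dtype=float))
    np.fill_diagonal(w, 0.0)
    w_hat = w / w.max()
    out = np.zeros(r)
    for i in range(r):
        k = int(np.count_nonzero(w[i]))
        if k < 2:
            continue
        s = 0.0
        for j in range(r):
            for h in range(r):
                if j == i or h == i or j == h:
                    continue
                s += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def fuse_quadruple_loop(mats, labels, n_iter, normalize=False):
    """Direct transcription of the fusion update with explicit loops.

    ``mats``: list of N x N arrays; ``labels``: length-N vector.
    Returns the fused matrix after ``n_iter`` iterations (off-diagonal
    modality average, zero diagonal).
    """
    labels = np.asarray(labels)
    n = mats[0].shape[0]
    m = len(mats)
    cls_idx = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}

    A = []
    for w in mats:
        a = np.zeros((n, n))
        for i in range(n):
            ci = cls_idx[labels[i]]
            denom = sum(w[i, k] for k in ci)
            if denom > 0:
                for j in ci:
                    if j != i:
                        a[i, j] = w[i, j] / denom
        A.append(a)

    W = [w.copy() for w in mats]
    for _ in range(n_iter):
        new = []
        for q in range(m):
            other = sum(W[p] for p in range(m) if p != q)
            upd = np.zeros((n, n))
            for i in range(n):
                ci = cls_idx[labels[i]]
                for j in range(n):
                    s = 0.0
                    for k in ci:
                        for l in ci:
                            s += A[q][i, k] * A[q][j, l] * other[k, l] / (m - 1)
                    upd[i, j] = s
            if normalize:
                deg = upd.sum(axis=1)
                inv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
                upd = inv[:, None] * upd * inv[None, :]
            new.append(upd)
        W = new
    fused = sum(W) / m
    np.fill_diagonal(fused, 0.0)
    return fused
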