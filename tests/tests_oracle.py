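"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written long-hand with explicit per-fold loops so they share
no code path with the package.
"""

import numpy as np


def oracle_q2(X, y, fold_assignment, n_ortho, leak_scaling=False):
    """Out-of-fold Q2 via explicit per-fold NIPALS with in-fold rescaling."""
    X = np.asarray(X, dtype=float)
    yv = np.where(y == np.unique(y)[1], 1.0, -1.0)
    yc_all = yv - yv.mean()
    preds = np.empty_like(yv)
    full_mean, full_sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    for k in np.unique(fold_assignment):
        tr, te = fold_assignment != k, fold_assignment == k
        if leak_scaling:
            mean, sd = full_mean, full_sd
        else:
            mean, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=1)
        Xtr, Xte = (X[tr] - mean) / sd, (X[te] - mean) / sd
        ytr = yv[tr] - yv[tr].mean()
        for _ in range(n_ortho):
            w = Xtr.T @ ytr
            w /= np.linalg.norm(w)
            t = Xtr @ w
            p = Xtr.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            w_o /= np.linalg.norm(w_o)
            t_o = Xtr @ w_o
            p_o = Xtr.T @ t_o / (t_o @ t_o)
            Xtr = Xtr - np.outer(t_o, p_o)
            Xte = Xte - np.outer(Xte @ w_o, p_o)
        w = Xtr.T @ ytr
        w /= np.linalg.norm(w)
        t = Xtr @ w
        q = (ytr @ t) / (t @ t)
        preds[te] = (Xte @ w) * q + yv[tr].mean() - yv.mean()
    press = float((yc_all - preds) @ (yc_all - preds))
    return 1.0 - press / float(yc_all @ yc_all)
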