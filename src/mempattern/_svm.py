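"""Numba kernels for the linear soft-margin SVM and searchlight scoring.

The binary solver is dual coordinate descent on the L1-hinge SVM dual
(liblinear-style), with the bias handled as an augmented constant feature.
Sweep order is shuffled each pass with a deterministic xorshift generator so
fits are bit-reproducible.  The one-vs-one multiclass vote (majority vote;
ties broken by largest summed signed margin, then lowest class id) and the
inner-cross-validated searchlight scoring loop live here too, because the
selection stage runs the solver tens of thousands of times per subject.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: fixed seed for the coordinate-sweep shuffle; fits are deterministic.
SWEEP_SEED = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def dcd_fit(Xb, y, Cvec, tol, max_iter):
    """Dual coordinate descent for min_w 0.5*||w||^2 + sum C_i hinge(y_i w.x_i).

    ``Xb`` is (n, d+1) with a trailing all-ones bias column; ``y`` is +/-1;
    ``Cvec`` holds the per-trial misclassification cost (a constant vector
    reproduces the plain C-SVM; class-balanced costs remove the bias a
    class-imbalanced training set induces on noise data).  Returns
    (w, n_iter, converged); stopping rule is the projected-gradient gap over
    one full sweep falling below ``tol``.
    """
    n, d1 = Xb.shape
    w = np.zeros(d1)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d1):
            s += Xb[i, j] * Xb[i, j]
        qii[i] = s
    idx = np.arange(n)
    state = SWEEP_SEED
    for it in range(max_iter):
        for k in range(n - 1, 0, -1):  # Fisher-Yates
            state = _xorshift(state)
            r = int(state % np.uint64(k + 1))
            t = idx[k]
            idx[k] = idx[r]
            idx[r] = t
        max_pg = -1.0e300
        min_pg = 1.0e300
        for k in range(n):
            i = idx[k]
            dot = 0.0
            for j in range(d1):
                dot += w[j] * Xb[i, j]
            g = y[i] * dot - 1.0
            a = alpha[i]
            Ci = Cvec[i]
            pg = g
            if a <= 0.0 and g > 0.0:
                pg = 0.0
            elif a >= Ci and g < 0.0:
                pg = 0.0
            if pg > max_pg:
                max_pg = pg
            if pg < min_pg:
                min_pg = pg
            if pg != 0.0:
                anew = min(max(a - g / qii[i], 0.0), Ci)
                da = anew - a
                if da != 0.0:
                    alpha[i] = anew
                    yda = da * y[i]
                    for j in range(d1):
                        w[j] += yda * Xb[i, j]
        if max_pg - min_pg < tol:
            return w, it + 1, True
    return w, max_iter, False


@njit(cache=True)
def fit_pairs(X, ycodes, n_classes, C, balanced, tol, max_iter):
    """One binary SVM per unordered class pair on the pair's trial subset.

    ``ycodes`` holds class codes 0..n_classes-1.  Pair p = (a, b), a < b, in
    lexicographic order; the binary target is +1 for class a.  With
    ``balanced`` the per-trial cost is C * n_pair / (2 * n_class), so both
    classes carry equal total cost however many trials each contributes.
    Returns (W, converged) with W of shape (n_pairs, d+1) (last entry = bias).
    """
    n, d = X.shape
    n_pairs = n_classes * (n_classes - 1) // 2
    W = np.zeros((n_pairs, d + 1))
    conv = np.zeros(n_pairs, dtype=np.bool_)
    p = 0
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            na = 0
            nb = 0
            for i in range(n):
                if ycodes[i] == a:
                    na += 1
                elif ycodes[i] == b:
                    nb += 1
            cnt = na + nb
            Ca = C
            Cb = C
            if balanced and na > 0 and nb > 0:
                Ca = C * cnt / (2.0 * na)
                Cb = C * cnt / (2.0 * nb)
            Xb = np.empty((cnt, d + 1))
            yb = np.empty(cnt)
            Cv = np.empty(cnt)
            k = 0
            for i in range(n):
                if ycodes[i] == a or ycodes[i] == b:
                    for j in range(d):
                        Xb[k, j] = X[i, j]
                    Xb[k, d] = 1.0
                    if ycodes[i] == a:
                        yb[k] = 1.0
                        Cv[k] = Ca
                    else:
                        yb[k] = -1.0
                        Cv[k] = Cb
                    k += 1
            w, _it, ok = dcd_fit(Xb, yb, Cv, tol, max_iter)
            W[p] = w
            conv[p] = ok
            p += 1
    return W, conv


@njit(cache=True)
def vote_predict(W, X, n_classes):
    """One-vs-one majority vote over pairwise linear decisions.

    Decision value > 0 votes for the pair's first (lower-id) class.  Vote
    ties break by the largest summed signed margin, then by the lowest class
    code.  Returns predicted class codes 0..n_classes-1.
    """
    n, d = X.shape
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        votes = np.zeros(n_classes)
        margin = np.zeros(n_classes)
        p = 0
        for a in range(n_classes):
            for b in range(a + 1, n_classes):
                dec = W[p, d]
                for j in range(d):
                    dec += W[p, j] * X[i, j]
                if dec > 0.0:
                    votes[a] += 1.0
                else:
                    votes[b] += 1.0
                margin[a] += dec
                margin[b] -= dec
                p += 1
        best = 0
        for c in range(1, n_classes):
            if votes[c] > votes[best] or (
                votes[c] == votes[best]
                and margin[c] > margin[best]
            ):
                best = c
        out[i] = best
    return out


@njit(cache=True)
def score_searchlights_kernel(
    X,
    ycodes,
    n_classes,
    fold_train,
    fold_train_off,
    fold_test,
    fold_test_off,
    neigh,
    neigh_off,
    min_neighborhood,
    C,
    balanced,
    tol,
    max_iter,
):
    """Inner-CV accuracy of every voxel's searchlight neighborhood.

    ``X`` is the full (trials, voxels) matrix.  Folds and neighborhoods are
    flattened index arrays with offset vectors (CSR-style).  Per fold, every
    column is z-scored with training statistics; per voxel, the neighborhood
    columns are gathered and a one-vs-one SVM is trained and tested.  Returns
    (correct, tested) counts per voxel; neighborhoods smaller than
    ``min_neighborhood`` stay at zero correct.
    """
    n, V = X.shape
    n_folds = len(fold_train_off) - 1
    correct = np.zeros(V, dtype=np.int64)
    tested = np.zeros(V, dtype=np.int64)
    for f in range(n_folds):
        tr = fold_train[fold_train_off[f] : fold_train_off[f + 1]]
        te = fold_test[fold_test_off[f] : fold_test_off[f + 1]]
        ntr = len(tr)
        nte = len(te)
        mu = np.zeros(V)
        sd = np.zeros(V)
        for j in range(V):
            s = 0.0
            for k in range(ntr):
                s += X[tr[k], j]
            m = s / ntr
            v = 0.0
            for k in range(ntr):
                dif = X[tr[k], j] - m
                v += dif * dif
            mu[j] = m
            s2 = np.sqrt(v / ntr)
            sd[j] = s2 if s2 > 0.0 else 1.0
        ytr = ycodes[tr]
        yte = ycodes[te]
        for vx in range(V):
            cols = neigh[neigh_off[vx] : neigh_off[vx + 1]]
            m = len(cols)
            if m < min_neighborhood:
                tested[vx] += nte
                continue
            Xtr = np.empty((ntr, m))
            Xte = np.empty((nte, m))
            for jj in range(m):
                c = cols[jj]
                for k in range(ntr):
                    Xtr[k, jj] = (X[tr[k], c] - mu[c]) / sd[c]
                for k in range(nte):
                    Xte[k, jj] = (X[te[k], c] - mu[c]) / sd[c]
            W, _conv = fit_pairs(Xtr, ytr, n_classes, C, balanced, tol, max_iter)
            pred = vote_predict(W, Xte, n_classes)
            for k in range(nte):
                if pred[k] == yte[k]:
                    correct[vx] += 1
            tested[vx] += nte
    return correct, tested


def warmup() -> None:
    """Trigger JIT compilation on a tiny problem (first call in a process)."""
    X = np.ascontiguousarray(np.random.default_rng(0).normal(size=(12, 3)))
    y = np.array([0, 1, 2] * 4, dtype=np.int64)
    W, _ = fit_pairs(X, y, 3, 1.0, True, 1e-4, 50)
    vote_predict(W, X, 3)
    off = np.array([0, 3], dtype=np.int64)
    cols = np.array([0, 1, 2], dtype=np.int64)
    tr = np.arange(8, dtype=np.int64)
    te = np.arange(8, 12, dtype=np.int64)
    foff = np.array([0, 8], dtype=np.int64)
    toff = np.array([0, 4], dtype=np.int64)
    score_searchlights_kernel(
        X, y, 3, tr, foff, te, toff, cols, off, 1, 1.0, True, 1e-4, 50
    )
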