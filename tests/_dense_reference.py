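"""Independent dense reference implementations used as test oracles.

Everything here is written as plain triple loops over dense arrays, straight
from the defining formulas, deliberately sharing no code with the package's
sparse/implicit implementation.
"""

from __future__ import annotations

import numpy as np


def dense_tensor(n, edges, domain_pairs, go_pairs, clip=True):
    """Dense (n, n, 3) relation tensor via literal all-pairs evaluation.

    ``edges`` are unordered index pairs; ``domain_pairs`` / ``go_pairs`` are
    (protein_index, term) pairs already restricted to the index.
    """
    neighbors = [set() for _ in range(n)]
    for i, j in edges:
        neighbors[i].add(j)
        neighbors[j].add(i)
    doms = [set() for _ in range(n)]
    for i, d in domain_pairs:
        doms[i].add(d)
    gos = [set() for _ in range(n)]
    for i, g in go_pairs:
        gos[i].add(g)

    # per-protein domain score: rarity-weighted count, min-max scaled
    all_domains = set(d for _, d in domain_pairs)
    np_d = {d: sum(1 for i in range(n) if d in doms[i]) for d in all_domains}
    raw = np.array([sum(1.0 / np_d[d] for d in doms[i]) for i in range(n)])
    if raw.max() > raw.min():
        pd = (raw - raw.min()) / (raw.max() - raw.min())
    else:
        pd = np.zeros(n)

    T = np.zeros((n, n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ni, nj = neighbors[i], neighbors[j]
            if len(ni) > 1 and len(nj) > 1 and ni & nj:
                w = len(ni & nj) ** 2 / ((len(ni) - 1) * (len(nj) - 1))
                T[i, j, 0] = min(w, 1.0) if clip else w
            if doms[i] & doms[j]:
                T[i, j, 1] = pd[i] * pd[j]
            if gos[i] and gos[j] and gos[i] & gos[j]:
                T[i, j, 2] = len(gos[i] & gos[j]) / np.sqrt(len(gos[i]) * len(gos[j]))
    return T


def dense_transitions(T):
    """Dense fiber-normalized transition tensors with explicit fallbacks."""
    n, _, m = T.shape
    Ta = np.empty_like(T)
    Th = np.empty_like(T)
    Te = np.empty_like(T)
    for k in range(m):
        for j in range(n):
            s = T[:, j, k].sum()
            Ta[:, j, k] = T[:, j, k] / s if s > 0 else 1.0 / n
        for i in range(n):
            s = T[i, :, k].sum()
            Th[i, :, k] = T[i, :, k] / s if s > 0 else 1.0 / n
    for i in range(n):
        for j in range(n):
            s = T[i, j, :].sum()
            Te[i, j, :] = T[i, j, :] / s if s > 0 else 1.0 / m
    return Ta, Th, Te


def dense_iterate(va, vh, ve, Ta, Th, Te, d, alpha, normalize=True):
    """One sequential VA -> VH -> VE update on dense tensors."""
    va_new = (1 - alpha) * d + alpha * np.einsum("ijk,j,k->i", Ta, vh, ve)
    if normalize:
        va_new = va_new / va_new.sum()
    vh_new = np.einsum("ijk,i,k->j", Th, va_new, ve)
    if normalize:
        vh_new = vh_new / vh_new.sum()
    ve_new = np.einsum("ijk,i,j->k", Te, va_new, vh_new)
    if normalize:
        ve_new = ve_new / ve_new.sum()
    return va_new, vh_new, ve_new


def dense_run(T, d, alpha, epsilon, max_iter, normalize=True):
    """Full dense power iteration; returns (va, vh, ve, converged, iters)."""
    n, _, m = T.shape
    Ta, Th, Te = dense_transitions(T)
    va, vh, ve = np.full(n, 1 / n), np.full(n, 1 / n), np.full(m, 1 / m)
    for it in range(1, max_iter + 1):
        va2, vh2, ve2 = dense_iterate(va, vh, ve, Ta, Th, Te, d, alpha, normalize)
        change = np.abs(va2 - va).sum() + np.abs(vh2 - vh).sum() + np.abs(ve2 - ve).sum()
        va, vh, ve = va2, vh2, ve2
        if change < epsilon:
            return va, vh, ve, True, it
    return va, vh, ve, False, max_iter


def dense_personalized_hits(W, d, alpha, n_iters, normalize=True):
    """Matrix-flavoured personalized HITS trajectory for a single relation.

    ``W`` is the n x n relation matrix.  Columns (rows) summing to zero use
    the uniform 1/n fallback.  Returns the list of (va, vh) after each of
    ``n_iters`` sequential updates.
    """
    n = W.shape[0]
    colsum = W.sum(axis=0)
    rowsum = W.sum(axis=1)
    Wa = np.empty_like(W, dtype=float)
    Wh = np.empty_like(W, dtype=float)
    for j in range(n):
        Wa[:, j] = W[:, j] / colsum[j] if colsum[j] > 0 else 1.0 / n
    for i in range(n):
        Wh[i, :] = W[i, :] / rowsum[i] if rowsum[i] > 0 else 1.0 / n
    va, vh = np.full(n, 1 / n), np.full(n, 1 / n)
    out = []
    for _ in range(n_iters):
        va = (1 - alpha) * d + alpha * (Wa @ vh)
        if normalize:
            va = va / va.sum()
        vh = Wh.T @ va
        if normalize:
            vh = vh / vh.sum()
        out.append((va.copy(), vh.copy()))
    return out


def materialize_transitions(tt):
    """Dense Ta/Th/Te from the package's implicit TransitionTensors."""
    n, m = tt.n, tt.m
    Ta = np.empty((n, n, m))
    Th = np.empty((n, n, m))
    Te = np.empty((n, n, m))
    support = np.asarray(tt.pair_support.todense()) > 0
    for k in range(m):
        A = np.asarray(tt.authority[k].todense())
        A[:, tt.zero_cols[k]] = 1.0 / n
        Ta[:, :, k] = A
        H = np.asarray(tt.hub[k].todense())
        H[tt.zero_rows[k], :] = 1.0 / n
        Th[:, :, k] = H
        E = np.asarray(tt.edge[k].todense())
        E[~support] = 1.0 / m
        Te[:, :, k] = E
    return Ta, Th, Te


def random_relation_tensor(rng, n, m=3, density=0.15, zero_slice_prob=0.15):
    """Random symmetric dense (n, n, m) tensor with empty diagonal.

    Some slices come out all-zero and many fibers are zero, so both the
    normalized and uniform-fallback branches get exercised.
    """
    T = np.zeros((n, n, m))
    for k in range(m):
        if rng.random() < zero_slice_prob:
            continue
        mask = rng.random((n, n)) < density
        vals = rng.random((n, n))
        U = np.triu(mask * vals, k=1)
        T[:, :, k] = U + U.T
    return T
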