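"""Independent brute-force reference implementations.

Every function here recomputes a statistic from its definition with plain
loops (or textbook closed forms), deliberately sharing no code with the
package, so tests can check the vectorized implementations against an
independent route.
"""

from __future__ import annotations

import math

import numpy as np


def moran_naive(x, W):
    """Moran's I by the O(N^2) double sum; W is a dense weight matrix."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    n = len(x)
    xb = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xb) * (x[j] - xb)
    den = sum((xi - xb) ** 2 for xi in x)
    return (n / W.sum()) * num / den


def bivariate_moran_naive(x, y, W):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    W = np.asarray(W, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xb) * (y[j] - yb)
    den = math.sqrt(sum((xi - xb) ** 2 for xi in x)) * math.sqrt(
        sum((yi - yb) ** 2 for yi in y)
    )
    return (n / W.sum()) * num / den


def _comb2(n):
    return n * (n - 1) / 2.0


def ari_naive(a, b):
    """Adjusted Rand index by the pair-counting contingency formula."""
    a = list(a)
    b = list(b)
    la = sorted(set(a))
    lb = sorted(set(b))
    nij = np.zeros((len(la), len(lb)))
    for x, y in zip(a, b):
        nij[la.index(x), lb.index(y)] += 1
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    n = len(a)
    sum_ij = sum(_comb2(v) for v in nij.ravel())
    sum_a = sum(_comb2(v) for v in ai)
    sum_b = sum(_comb2(v) for v in bj)
    expected = sum_a * sum_b / _comb2(n)
    maxi = 0.5 * (sum_a + sum_b)
    if maxi == expected:
        return 1.0
    return (sum_ij - expected) / (maxi - expected)


def nmi_naive(a, b):
    """Mutual information over arithmetic-mean entropy, by p log p sums."""
    a = list(a)
    b = list(b)
    n = len(a)
    la = sorted(set(a))
    lb = sorted(set(b))
    mi = 0.0
    for x in la:
        for y in lb:
            nij = sum(1 for u, v in zip(a, b) if u == x and v == y)
            if nij:
                pij = nij / n
                pi = sum(1 for u in a if u == x) / n
                pj = sum(1 for v in b if v == y) / n
                mi += pij * math.log(pij / (pi * pj))
    ha = -sum(
        (a.count(x) / n) * math.log(a.count(x) / n) for x in la
    )
    hb = -sum(
        (b.count(y) / n) * math.log(b.count(y) / n) for y in lb
    )
    denom = 0.5 * (ha + hb)
    if denom == 0:
        return 1.0
    return mi / denom


def transition_matrix_naive(labels, W):
    """Ordered neighbor-pair transition frequencies by enumeration."""
    labels = list(labels)
    doms = sorted(set(labels), key=str)
    K = len(doms)
    counts = np.zeros((K, K))
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                counts[doms.index(labels[i]), doms.index(labels[j])] += 1
    tm = np.full((K, K), 1.0 / K)
    for r in range(K):
        if counts[r].sum() > 0:
            tm[r] = counts[r] / counts[r].sum()
    return tm, doms


def centralities_naive(labels, W):
    """G1/G2/G3 per domain by direct set enumeration and BFS."""
    labels = list(labels)
    W = np.asarray(W)
    n = len(labels)
    doms = sorted(set(labels), key=str)
    adj = [set(np.nonzero(W[i] > 0)[0].tolist()) for i in range(n)]
    out = np.zeros((len(doms), 3))
    for k, d in enumerate(doms):
        members = {i for i, lab in enumerate(labels) if lab == d}
        # G1
        boundary = set()
        for v in members:
            boundary |= adj[v]
        boundary -= members
        out[k, 0] = len(boundary) / (n - len(members))
        # G2: local clustering coefficient
        cc = []
        for v in members:
            nb = sorted(adj[v])
            deg = len(nb)
            if deg < 2:
                cc.append(0.0)
                continue
            t = 0
            for ii in range(deg):
                for jj in range(ii + 1, deg):
                    if nb[jj] in adj[nb[ii]]:
                        t += 1
            cc.append(2.0 * t / (deg * (deg - 1)))
        out[k, 1] = float(np.mean(cc))
        # G3: BFS distance from the member set
        dist = {v: 0 for v in members}
        frontier = list(members)
        d_cur = 0
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if u not in dist:
                        dist[u] = d_cur + 1
                        nxt.append(u)
            frontier = nxt
            d_cur += 1
        dsum = sum(dv for v, dv in dist.items() if v not in members)
        reached = sum(1 for v in dist if v not in members)
        out[k, 2] = reached / dsum if dsum > 0 else 0.0
    return out, doms


def tmm_naive(yk, yr, trim_m=0.30, trim_a=0.05):
    """TMM factor of one test library against a reference, by sorting."""
    yk = np.asarray(yk, float)
    yr = np.asarray(yr, float)
    Nk, Nr = yk.sum(), yr.sum()
    ok = (yk > 0) & (yr > 0)
    M, A, wt = [], [], []
    for g in np.nonzero(ok)[0]:
        lk = math.log2(yk[g] / Nk)
        lr = math.log2(yr[g] / Nr)
        M.append(lk - lr)
        A.append(0.5 * (lk + lr))
        wt.append(
            (Nk - yk[g]) / (Nk * yk[g]) + (Nr - yr[g]) / (Nr * yr[g])
        )
    M, A, wt = np.array(M), np.array(A), np.array(wt)
    n = len(M)
    loM = int(np.floor(n * trim_m))
    loA = int(np.floor(n * trim_a))
    rM = np.argsort(np.argsort(M, kind="stable"), kind="stable")
    rA = np.argsort(np.argsort(A, kind="stable"), kind="stable")
    keep = (rM >= loM) & (rM < n - loM) & (rA >= loA) & (rA < n - loA)
    if wt[keep].sum() > 0:
        f = float(wt[keep] @ M[keep]) / float(wt[keep].sum())
    else:
        f = float(M[keep].mean())
    return 2.0**f


def rmse_naive(T, P):
    T = np.asarray(T, float)
    P = np.asarray(P, float)
    K = T.shape[1]
    acc = 0.0
    for k in range(K):
        S = T[:, k].sum()
        acc += sum((P[i, k] - T[i, k]) ** 2 for i in range(T.shape[0])) / S
    return math.sqrt(acc / K)


def jsd_naive(T, P):
    T = np.asarray(T, float)
    P = np.asarray(P, float)
    vals = []
    for k in range(T.shape[1]):
        qt = T[:, k] / T[:, k].sum()
        qp = P[:, k] / P[:, k].sum()
        m = 0.5 * (qt + qp)
        kl_t = sum(
            qt[i] * math.log(qt[i] / m[i]) for i in range(len(qt)) if qt[i] > 0
        )
        kl_p = sum(
            qp[i] * math.log(qp[i] / m[i]) for i in range(len(qp)) if qp[i] > 0
        )
        vals.append(0.5 * kl_t + 0.5 * kl_p)
    return float(np.mean(vals))


def cosine_naive(A, B):
    a = np.asarray(A, float).ravel()
    b = np.asarray(B, float).ravel()
    return float(
        sum(x * y for x, y in zip(a, b))
        / (math.sqrt(sum(x * x for x in a)) * math.sqrt(sum(y * y for y in b)))
    )


def mantel_naive(A, B):
    a = np.asarray(A, float).ravel()
    b = np.asarray(B, float).ravel()
    ab, bb = a.mean(), b.mean()
    num = sum((x - ab) * (y - bb) for x, y in zip(a, b))
    den = math.sqrt(
        sum((x - ab) ** 2 for x in a) * sum((y - bb) ** 2 for y in b)
    )
    return num / den


def cindex_naive(t, p):
    t = list(t)
    p = list(p)
    num = 0.0
    den = 0
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[i] == t[j]:
                continue
            den += 1
            if p[i] == p[j]:
                num += 0.5
            elif (t[i] < t[j]) == (p[i] < p[j]):
                num += 1.0
    return num / den


def ols_coefs_naive(y, groups):
    """Treatment-coded OLS coefficients via the normal equations."""
    y = np.asarray(y, float)
    levels = sorted(set(groups))
    X = np.ones((len(y), len(levels)))
    for col, lev in enumerate(levels[1:], start=1):
        X[:, col] = [1.0 if g == lev else 0.0 for g in groups]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta, levels


def pearson_naive(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab, bb = a.mean(), b.mean()
    num = sum((x - ab) * (y - bb) for x, y in zip(a, b))
    den = math.sqrt(
        sum((x - ab) ** 2 for x in a) * sum((y - bb) ** 2 for y in b)
    )
    return num / den


def kde_ise_quadrature(x, y, hx, hy, n_grid=8001):
    """Trapezoid quadrature of the integrated squared KDE difference (1D)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = min(x.min() - 8 * hx, y.min() - 8 * hy)
    hi = max(x.max() + 8 * hx, y.max() + 8 * hy)
    grid = np.linspace(lo, hi, n_grid)

    def dens(pts, h):
        out = np.zeros_like(grid)
        for p in pts:
            out += np.exp(-0.5 * ((grid - p) / h) ** 2) / (
                h * math.sqrt(2 * math.pi)
            )
        return out / len(pts)

    diff = dens(x, hx) - dens(y, hy)
    return float(np.trapezoid(diff**2, grid))
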