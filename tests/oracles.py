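"""Independent brute-force reference implementations.

Everything here is deliberately naive (explicit Python loops, no linear
algebra shortcuts) and stays independent of the code paths it checks.
"""

import itertools
import math

import numpy as np


def oracle_adjacency(snapshot, d, num_nodes):
    """Triple-loop co-membership counts for one order."""
    a = np.zeros((num_nodes, num_nodes), dtype=np.int64)
    for edge in snapshot:
        if len(edge) != d:
            continue
        for i in edge:
            for j in edge:
                if i != j:
                    a[i, j] += 1
    return a


def oracle_adjacency_stack(th, d):
    return np.stack([oracle_adjacency(s, d, th.num_nodes) for s in th.snapshots])


def oracle_annealed(th, d):
    mats = oracle_adjacency_stack(th, d)
    total = np.zeros(mats.shape[1:], dtype=float)
    for t in range(mats.shape[0]):
        total += mats[t]
    return total / mats.shape[0]


def oracle_cross_matrix(th, d1, d2, tau):
    """Nested-loop lag-tau cross-covariance matrix between two orders."""
    a1 = oracle_adjacency_stack(th, d1).astype(float)
    a2 = oracle_adjacency_stack(th, d2).astype(float)
    mu1 = oracle_annealed(th, d1)
    mu2 = oracle_annealed(th, d2)
    t_len, n = a1.shape[0], a1.shape[1]
    out = np.zeros((n, n))
    for t in range(t_len - tau):
        x = a1[t] - mu1
        y = a2[t + tau] - mu2
        for i in range(n):
            for k in range(n):
                s = 0.0
                for j in range(n):
                    s += x[i, j] * y[k, j]
                out[i, k] += s
    norm = (t_len - tau) * math.factorial(d1 - 1) * math.factorial(d2 - 1)
    return out / norm


def oracle_cross_trace(th, d1, d2, tau):
    mat = oracle_cross_matrix(th, d1, d2, tau)
    return float(sum(mat[i, i] for i in range(mat.shape[0])))


def oracle_intra_matrix(th, d, tau):
    return oracle_cross_matrix(th, d, d, tau)


def oracle_intra_trace(th, d, tau):
    return oracle_cross_trace(th, d, d, tau)


def oracle_gap(th, d1, d2, tau):
    c12 = oracle_cross_trace(th, d1, d2, tau)
    c21 = oracle_cross_trace(th, d2, d1, tau)
    s1 = oracle_intra_trace(th, d1, 0)
    s2 = oracle_intra_trace(th, d2, 0)
    return (c12 - c21) / (2.0 * math.sqrt(s1 * s2))


def oracle_binned(lags, values, edges, geometric):
    """Direct per-bin mean / population std recomputation."""
    out = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        if b == len(edges) - 2:
            sub = [v for lag, v in zip(lags, values) if lo <= lag <= hi]
        else:
            sub = [v for lag, v in zip(lags, values) if lo <= lag < hi]
        if not sub:
            continue
        mean = sum(sub) / len(sub)
        var = sum((v - mean) ** 2 for v in sub) / len(sub)
        center = math.sqrt(lo * hi) if geometric else 0.5 * (lo + hi)
        out.append((center, mean, math.sqrt(var), len(sub)))
    return out


def oracle_maximal_cliques(edges, num_nodes):
    """All maximal cliques (size >= 2) by exhaustive subset enumeration."""
    edge_set = {frozenset(e) for e in edges}
    nodes = sorted({n for e in edges for n in e})

    def is_clique(sub):
        return all(frozenset(p) in edge_set for p in itertools.combinations(sub, 2))

    cliques = [
        frozenset(sub)
        for size in range(2, len(nodes) + 1)
        for sub in itertools.combinations(nodes, size)
        if is_clique(sub)
    ]
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    return set(maximal)


def oracle_autocorrelation(series, tau):
    """Plain sample autocorrelation of one binary series at lag tau."""
    x = np.asarray(series, dtype=float)
    mean = x.mean()
    num = float(np.sum((x[: len(x) - tau] - mean) * (x[tau:] - mean)))
    den = float(np.sum((x - mean) ** 2))
    return num / den if den > 0 else float("nan")
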