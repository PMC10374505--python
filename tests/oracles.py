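"""Brute-force reference implementations for the graph-measure suite.

Everything here is written for clarity and independence, not speed:
shortest paths by exhaustive simple-path enumeration, triangles and
triplets by explicit loops, modularity by exhaustive partition search,
assortativity from the raw edge-end value lists. Usable up to ~8 nodes.
"""

from __future__ import annotations

import math

import numpy as np


def lengths_bruteforce(W):
    n = W.shape[0]
    L = np.full((n, n), np.inf)
    for i in range(n):
        L[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j]
    return L


def shortest_paths_bruteforce(L):
    """All-pairs shortest paths by enumerating every simple path."""
    n = L.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = list(range(n))

    def dfs(current, target, visited, cost):
        if cost >= D[start, target]:
            pass
        if current == target:
            D[start, target] = min(D[start, target], cost)
            return
        for nxt in nodes:
            if nxt not in visited and np.isfinite(L[current, nxt]):
                visited.add(nxt)
                dfs(nxt, target, visited, cost + L[current, nxt])
                visited.remove(nxt)

    for start in range(n):
        for target in range(n):
            if start != target:
                dfs(start, target, {start}, 0.0)
    return D


def path_measures_bruteforce(D):
    n = D.shape[0]
    finite, inv, ecc = [], [], []
    for i in range(n):
        worst = -math.inf
        for j in range(n):
            if i == j:
                continue
            d = D[i, j]
            if math.isfinite(d):
                finite.append(d)
                inv.append(1.0 / d)
            else:
                inv.append(0.0)
            worst = max(worst, d)
        ecc.append(worst)
    return {
        "characteristic_path_length": sum(finite) / len(finite),
        "global_efficiency": sum(inv) / (n * (n - 1)),
        "eccentricity": sum(ecc) / n,
        "radius": min(ecc),
        "diameter": max(ecc),
    }


def degree_strength_bruteforce(W, tau):
    n = W.shape[0]
    degrees = [sum(1 for j in range(n) if j != i and W[i, j] > tau) for i in range(n)]
    strengths = [sum(W[i, j] for j in range(n) if j != i) for i in range(n)]
    return {
        "average_degree": sum(degrees) / n,
        "strength": sum(strengths) / n,
    }


def clustering_bruteforce(W):
    """Onnela weighted clustering, transitivity and local efficiency."""
    n = W.shape[0]
    tri = np.zeros(n)
    triplets = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > 0)
        triplets[i] = k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    tri[i] += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
    c = [tri[i] / triplets[i] if triplets[i] > 0 else 0.0 for i in range(n)]
    total_triplets = triplets.sum()
    eloc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = shortest_paths_bruteforce(lengths_bruteforce(sub))
        m = len(nbrs)
        acc = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and math.isfinite(D[a, b]) and D[a, b] > 0:
                    acc += 1.0 / D[a, b]
        eloc += acc / (m * (m - 1))
    return {
        "clustering_coefficient": sum(c) / n,
        "transitivity": float(tri.sum() / total_triplets) if total_triplets > 0 else 0.0,
        "local_efficiency": eloc / n,
    }


def _partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = [0] * n

    def rec(i, maxlab):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)  # node 0 fixed in community 0


def modularity_bruteforce(W, gamma=1.0):
    """Exhaustive search for the modularity optimum (n <= 8)."""
    n = W.shape[0]
    two_m = W.sum()
    s = W.sum(axis=1)
    best_q, best_part = -math.inf, None
    for part in _partitions(n):
        q = 0.0
        for i in range(n):
            for j in range(n):
                if part[i] == part[j]:
                    q += W[i, j] - gamma * s[i] * s[j] / two_m
        q /= two_m
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def modularity_of_partition_bruteforce(W, partition, gamma=1.0):
    n = W.shape[0]
    two_m = W.sum()
    s = W.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] == partition[j]:
                q += W[i, j] - gamma * s[i] * s[j] / two_m
    return q / two_m


def assortativity_bruteforce(W, tau):
    n = W.shape[0]
    s = [sum(W[i]) for i in range(n)]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > tau:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def auc_pair_counting(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def random_weighted_graph(n, density, rng, *, connected=False):
    """Seeded random symmetric weighted graph with weights in (0, 1]."""
    while True:
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
        if W.sum() == 0:
            continue
        if connected:
            D = shortest_paths_bruteforce(lengths_bruteforce(W))
            if not np.isfinite(D).all():
                continue
        return W
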