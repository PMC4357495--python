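"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over probabilities or
paths, deliberately sharing no code with the package internals, so
agreement is evidence of correctness rather than of shared bugs.
"""

import math
from itertools import product

import numpy as np


def ig_triple_loop(counts) -> tuple[float, float, float]:
    """(ig, mi, cmi) of a 3x3x2 table via direct summation of the defining
    formulas, cell by cell, in bits."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n

    mi = 0.0
    for x in range(3):
        for y in range(3):
            pxy = p[x, y, :].sum()
            px = p[x, :, :].sum()
            py = p[:, y, :].sum()
            if pxy > 0:
                mi += pxy * math.log2(pxy / (px * py))

    cmi = 0.0
    for z in range(2):
        pz = p[:, :, z].sum()
        if pz == 0:
            continue
        for x in range(3):
            for y in range(3):
                pxyz = p[x, y, z]
                if pxyz == 0:
                    continue
                pxy_z = pxyz / pz
                px_z = p[x, :, z].sum() / pz
                py_z = p[:, y, z].sum() / pz
                cmi += pxyz * math.log2(pxy_z / (px_z * py_z))
    return cmi - mi, mi, cmi


def shortest_path_matrix(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by Floyd-Warshall; inf when disconnected."""
    n = adjacency.shape[0]
    dist = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def path_counts(adjacency: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of distinct shortest s-t paths."""
    n = adjacency.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            for u in range(n):
                if adjacency[u, t] and dist[s, u] == dist[s, t] - 1:
                    sigma[s, t] += sigma[s, u]
    return sigma


def betweenness_brute(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via the pair-dependency definition:
    sum over unordered pairs (s, t), s != v != t, of sigma_st(v)/sigma_st,
    with sigma_st(v) = sigma_sv * sigma_vt when v lies on a shortest path."""
    n = adjacency.shape[0]
    dist = shortest_path_matrix(adjacency)
    sigma = path_counts(adjacency, dist)
    btw = np.zeros(n)
    for s, t in product(range(n), range(n)):
        if s >= t or not np.isfinite(dist[s, t]):
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw
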