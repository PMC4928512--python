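"""Independent brute-force oracles used to validate the graph metrics.

Deliberately naive implementations (triple-loop triangle counting,
exhaustive relaxation for shortest paths) that share no code with the
package's vectorized versions.
"""

from itertools import combinations

import numpy as np


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by explicit neighbour-pair enumeration."""
    a = adj > 0
    n = a.shape[0]
    cis = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            cis.append(0.0)
            continue
        links = sum(1 for u, v in combinations(nbrs, 2) if a[u, v])
        cis.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cis))


def brute_distances(adj: np.ndarray) -> np.ndarray:
    """Hop-count shortest paths by exhaustive repeated relaxation."""
    a = adj > 0
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for _ in range(n):
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if d[i, k] + d[k, j] < d[i, j]:
                        d[i, j] = d[i, k] + d[k, j]
    return d


def brute_L_E(adj: np.ndarray) -> tuple[float, float]:
    """Characteristic path length and global efficiency from brute paths."""
    d = brute_distances(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d[off])
    L = d[off][finite].mean()
    E = np.where(finite, 1.0 / d[off], 0.0).mean()
    return float(L), float(E)
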