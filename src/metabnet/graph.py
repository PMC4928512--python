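"""Density thresholding and small-world graph metrics.

Connectivity matrices are reduced to graphs by proportional thresholding:
the k = round(density * M) strongest of the M = N(N-1)/2 possible edges are
retained, so graphs compared across groups have equal density.  Metrics come
in two modes:

* ``binary`` — the printed textbook forms: local clustering
  C_i = 2 t_i / (k_i (k_i - 1)) with t_i triangles at node i, shortest paths
  as hop counts, global efficiency E = mean of 1/d_ij.
* ``weighted`` — Onnela clustering C_i = (1/(k_i(k_i-1))) sum (w'_ij w'_ih
  w'_jh)^(1/3) with weights rescaled by the maximum, and path lengths that
  sum 1/w over edges (strong correlation = short edge).

Small-worldness compares the real graph against degree-preserving rewired
null networks: gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda;
sigma > 1 marks small-world organization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "ThresholdedGraph",
    "DistanceMatrix",
    "NetworkMetrics",
    "SmallWorldEntry",
    "proportional_threshold",
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "network_metrics",
    "rewire_null",
    "small_worldness",
]

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class ThresholdedGraph:
    """Weighted or binary adjacency retained at a target density."""

    adjacency: np.ndarray
    density: float
    mode: str = "weighted"

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("no self-loops allowed")
        if self.mode not in ("binary", "weighted"):
            raise ValueError("mode must be 'binary' or 'weighted'")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_array(self) -> np.ndarray:
        """(k, 2) array of node-index pairs i < j for the retained edges."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j]).astype(np.int64)

    def weights(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return self.adjacency[i, j]


class DistanceMatrix(NamedTuple):
    """Pairwise shortest-path lengths; unreachable pairs are +inf."""

    d: np.ndarray


class NetworkMetrics(NamedTuple):
    """Global graph parameters of one thresholded network."""

    C: float  # clustering coefficient (mean of local C_i)
    E: float  # global efficiency
    L: float  # characteristic path length over reachable pairs
    n_nodes: int
    unreachable_fraction: float


class SmallWorldEntry(NamedTuple):
    """Small-world parameters against rewired null networks."""

    gamma: float  # C_real / C_rand
    lam: float  # L_real / L_rand
    sigma: float  # gamma / lam
    c_real: float
    c_rand: float
    l_real: float
    l_rand: float
    n_randomizations: int


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def threshold_adjacency(
    values: np.ndarray, density: float, mode: str = "weighted", ranking: str = "signed"
) -> np.ndarray:
    """Fast path: adjacency of the top-k edges of a correlation matrix.

    Ranking is by signed value by default (strongest positive correlations
    first); ``ranking="absolute"`` ranks by |r|.  Ties at the cut resolve by
    canonical (i, j) index order.  In weighted mode retained edges with
    non-positive weight are dropped (fractional powers and inverse lengths
    are undefined for them); binary mode keeps them as unit edges.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    m = n * (n - 1) // 2
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    k = _round_half_away(density * m)
    if k < 1:
        raise ValueError("density too low: no edges retained after rounding")
    if ranking not in ("signed", "absolute"):
        raise ValueError("ranking must be 'signed' or 'absolute'")
    iu = np.triu_indices(n, k=1)
    vals = values[iu]
    key = -np.abs(vals) if ranking == "absolute" else -vals
    order = np.lexsort((iu[1], iu[0], key))[:k]
    adj = np.zeros((n, n))
    ri, rj = iu[0][order], iu[1][order]
    if mode == "binary":
        adj[ri, rj] = 1.0
    else:
        w = vals[order]
        pos = w > 0
        if not pos.all():
            logger.debug("dropping %d non-positive retained edges", int((~pos).sum()))
        adj[ri[pos], rj[pos]] = w[pos]
    adj += adj.T
    return adj


def proportional_threshold(
    matrix: ConnectivityMatrix | np.ndarray,
    density: float,
    mode: str = "weighted",
    ranking: str = "signed",
) -> ThresholdedGraph:
    """Retain the top-ranked k = round(density * M) edges of a matrix."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    adj = threshold_adjacency(values, density, mode=mode, ranking=ranking)
    return ThresholdedGraph(adjacency=adj, density=density, mode=mode)


# --------------------------------------------------------------------- metrics

def _clustering(adj: np.ndarray, mode: str) -> np.ndarray:
    a = (adj > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if mode == "binary":
        cyc = np.einsum("ij,jk,ki->i", a, a, a)
    else:
        mx = adj.max()
        if mx <= 0:
            return np.zeros(adj.shape[0])
        s = np.cbrt(adj / mx)
        cyc = np.einsum("ij,jk,ki->i", s, s, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, cyc / np.where(denom > 0, denom, 1.0), 0.0)
    return ci


def clustering_coefficient(g: ThresholdedGraph) -> tuple[float, np.ndarray]:
    """Global clustering coefficient C (mean of local C_i) and the C_i."""
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    ci = _clustering(g.adjacency, g.mode)
    return float(ci.mean()), ci


def _distances(adj: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        graph = csr_matrix((adj > 0).astype(float))
        return _csgraph_shortest_path(graph, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)


def shortest_path_lengths(g: ThresholdedGraph) -> DistanceMatrix:
    """All-pairs shortest paths: hop counts (binary) or sums of 1/w (weighted)."""
    return DistanceMatrix(d=_distances(g.adjacency, g.mode))


def characteristic_path_length(d: DistanceMatrix) -> tuple[float, float]:
    """Mean shortest-path length over reachable ordered pairs.

    Returns ``(L, unreachable_fraction)``; disconnected pairs are excluded
    from the mean and reported as the fraction of ordered pairs.
    """
    dist = d.d
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = dist[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite off-diagonal distances")
    return float(vals[finite].mean()), float(1.0 - finite.mean())


def global_efficiency(d: DistanceMatrix) -> float:
    """Mean of 1/d_ij over ordered pairs i != j, with 1/inf = 0."""
    dist = d.d
    n = dist.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist[off]) & (dist[off] > 0), 1.0 / dist[off], 0.0)
    return float(inv.mean())


def network_metrics(adj: np.ndarray, mode: str = "weighted") -> NetworkMetrics:
    """C, E and L of an adjacency matrix in one pass (loop-friendly)."""
    ci = _clustering(adj, mode)
    dist = _distances(adj, mode)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = dist[off]
    finite = np.isfinite(vals)
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (vals > 0), 1.0 / vals, 0.0)
    l_val = float(vals[finite].mean()) if finite.any() else np.inf
    return NetworkMetrics(
        C=float(ci.mean()),
        E=float(inv.mean()),
        L=l_val,
        n_nodes=n,
        unreachable_fraction=float(1.0 - finite.mean()),
    )


# --------------------------------------------------------------------- nulls

def _swap_kernel_py(edges: np.ndarray, adj: np.ndarray, target: int, max_tries: int, seed: int) -> int:
    rng = np.random.default_rng(seed)
    k = edges.shape[0]
    accepted = 0
    tries = 0
    while accepted < target and tries < max_tries:
        tries += 1
        e1 = int(rng.integers(k))
        e2 = int(rng.integers(k))
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, c] = adj[c, a] = True
        adj[b, d] = adj[d, b] = True
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        accepted += 1
    return accepted


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _swap_kernel_nb(edges, adj, target, max_tries, seed):  # pragma: no cover
        np.random.seed(seed)
        k = edges.shape[0]
        accepted = 0
        tries = 0
        while accepted < target and tries < max_tries:
            tries += 1
            e1 = np.random.randint(0, k)
            e2 = np.random.randint(0, k)
            if e1 == e2:
                continue
            a = edges[e1, 0]
            b = edges[e1, 1]
            c = edges[e2, 0]
            d = edges[e2, 1]
            if np.random.random() < 0.5:
                t = c
                c = d
                d = t
            if a == c or a == d or b == c or b == d:
                continue
            if adj[a, c] or adj[b, d]:
                continue
            adj[a, b] = False
            adj[b, a] = False
            adj[c, d] = False
            adj[d, c] = False
            adj[a, c] = True
            adj[c, a] = True
            adj[b, d] = True
            adj[d, b] = True
            edges[e1, 0] = a
            edges[e1, 1] = c
            edges[e2, 0] = b
            edges[e2, 1] = d
            accepted += 1
        return accepted


def _rewire_edges(
    edges: np.ndarray, n_nodes: int, seed: int, swaps_per_edge: int = 10
) -> tuple[np.ndarray, int]:
    """Degree-preserving double-edge-swap randomization of an edge array.

    Dense graphs (more than half the possible edges) are rewired through
    their complement — swaps on the complement preserve the complement's
    degree sequence and hence the original one — which keeps the acceptance
    rate of proposed swaps workable at high density.
    """
    m = n_nodes * (n_nodes - 1) // 2
    use_complement = edges.shape[0] > m // 2
    if use_complement:
        full = np.zeros((n_nodes, n_nodes), dtype=bool)
        full[edges[:, 0], edges[:, 1]] = True
        iu = np.triu_indices(n_nodes, k=1)
        comp_mask = ~full[iu]
        work = np.column_stack([iu[0][comp_mask], iu[1][comp_mask]]).astype(np.int64)
    else:
        work = edges.copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[work[:, 0], work[:, 1]] = True
    adj |= adj.T
    k = work.shape[0]
    target = swaps_per_edge * max(k, 1)
    max_tries = 100 * target
    kernel = _swap_kernel_nb if _HAVE_NUMBA else _swap_kernel_py
    accepted = kernel(work, adj, target, max_tries, seed)
    if use_complement:
        iu = np.triu_indices(n_nodes, k=1)
        comp_adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        comp_adj[work[:, 0], work[:, 1]] = True
        comp_adj |= comp_adj.T
        keep = ~comp_adj[iu]
        # the original graph's edges are the complement of the rewired complement
        out = np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int64)
        return out, accepted
    return work, accepted


def rewire_null(
    g: ThresholdedGraph,
    n_randomizations: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[ThresholdedGraph]:
    """Degree-preserving rewired null networks (density conserved).

    In weighted mode the multiset of edge weights is preserved and
    reassigned uniformly at random to the rewired edges.  A graph admitting
    no valid swap (e.g. a star) falls back to density-only rewiring — k
    edges placed uniformly at random — with a warning.
    """
    n_edges = g.n_edges
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    m = n * (n - 1) // 2
    base_edges = g.edge_array()
    base_weights = g.weights()
    complete = n_edges == m
    nulls: list[ThresholdedGraph] = []
    warned = False
    for _ in range(n_randomizations):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if complete:
            edges = base_edges
        else:
            edges, accepted = _rewire_edges(base_edges, n, sub_seed, swaps_per_edge)
            if accepted == 0:
                if not warned:
                    logger.warning(
                        "graph admits no degree-preserving swap; "
                        "falling back to density-only rewiring"
                    )
                    warned = True
                iu = np.triu_indices(n, k=1)
                pick = rng.choice(m, size=n_edges, replace=False)
                edges = np.column_stack([iu[0][pick], iu[1][pick]]).astype(np.int64)
        adj = np.zeros((n, n))
        if g.mode == "weighted":
            w = rng.permutation(base_weights)
        else:
            w = np.ones(n_edges)
        adj[edges[:, 0], edges[:, 1]] = w
        adj += adj.T
        nulls.append(ThresholdedGraph(adjacency=adj, density=g.density, mode=g.mode))
    return nulls


def small_worldness(
    g: ThresholdedGraph,
    n_randomizations: int = 1000,
    seed: int = 0,
    null_graphs: list[ThresholdedGraph] | None = None,
) -> SmallWorldEntry:
    """gamma, lambda and sigma of a graph against rewired nulls.

    gamma = C_real / mean C over nulls, lambda = L_real / mean L over nulls,
    sigma = gamma / lambda.  The mean null parameters come from
    ``n_randomizations`` degree-preserving rewirings (or the provided null
    graphs).
    """
    real = network_metrics(g.adjacency, g.mode)
    if not np.isfinite(real.L):
        raise ValueError("graph has no finite path lengths")
    if null_graphs is None:
        null_graphs = rewire_null(g, n_randomizations, seed)
    null_c = np.empty(len(null_graphs))
    null_l = np.empty(len(null_graphs))
    for idx, null in enumerate(null_graphs):
        metrics = network_metrics(null.adjacency, null.mode)
        null_c[idx] = metrics.C
        null_l[idx] = metrics.L
    finite_l = null_l[np.isfinite(null_l)]
    c_rand = float(null_c.mean())
    l_rand = float(finite_l.mean()) if finite_l.size else np.inf
    if c_rand == 0 or l_rand == 0 or not np.isfinite(l_rand):
        raise ValueError("degenerate null: mean null C or L is zero or infinite")
    gamma = real.C / c_rand
    lam = real.L / l_rand
    return SmallWorldEntry(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(gamma / lam),
        c_real=real.C,
        c_rand=c_rand,
        l_real=real.L,
        l_rand=l_rand,
        n_randomizations=len(null_graphs),
    )
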