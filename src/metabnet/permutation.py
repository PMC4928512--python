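"""Non-parametric permutation tests on subtracted connectivity matrices.

Group labels are permuted over the pooled subjects (without replacement,
preserving group sizes); each relabeling yields a pair of connectivity
matrices and their difference.  Per-edge two-tailed p-values come from the
permutation distribution of |delta|, and familywise-corrected p-values from
the max-statistic distribution (the maximum |delta| over all edges per
permutation), the standard strong-control FWE for permutation tests.  Both
use +1 smoothing: p = (1 + #{perm >= observed}) / (n_permutations + 1), so
no p-value is ever zero.

When the number of distinct relabelings C(nA+nB, nA) does not exceed the
requested count, the scheme enumerates all of them (exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import correlation_matrix
from .series import SubjectSeries

__all__ = [
    "PermutationScheme",
    "make_scheme",
    "permute_edge_test",
    "EdgeTestResult",
    "SignificantEdgeSet",
    "significant_edges",
]

logger = logging.getLogger(__name__)

#: numerical slack when comparing permuted against observed statistics:
#: relabelings that reproduce the observed partition must count as ties even
#: though row-order changes perturb floating-point sums
_TIE_TOL = 1e-10


@dataclass
class PermutationScheme:
    """A reusable sequence of group relabelings over pooled subjects.

    ``labelings`` holds, per permutation, a permutation of the pooled
    subject indices: the first ``n_a`` entries are assigned to group A and
    the rest to group B.  Built once and shared between the edge test and
    the network-parameter test so both use identical relabelings.
    """

    n_a: int
    n_b: int
    seed: int
    labelings: np.ndarray
    exhaustive: bool = False

    @property
    def n_permutations(self) -> int:
        return self.labelings.shape[0]

    @property
    def n_pooled(self) -> int:
        return self.n_a + self.n_b

    def checksum(self) -> int:
        """Stable digest of the relabeling sequence (for reuse assertions)."""
        import zlib

        return zlib.crc32(np.ascontiguousarray(self.labelings).tobytes())


def make_scheme(
    n_a: int,
    n_b: int,
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive: str | bool = "auto",
) -> PermutationScheme:
    """Draw group relabelings, or enumerate all of them when feasible.

    With ``exhaustive="auto"`` (default) enumeration replaces Monte-Carlo
    sampling whenever C(n_a+n_b, n_a) <= n_permutations.
    """
    if n_a < 3 or n_b < 3:
        raise ValueError("each group needs at least 3 subjects")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    n = n_a + n_b
    n_distinct = comb(n, n_a)
    use_exhaustive = exhaustive is True or (
        exhaustive == "auto" and n_distinct <= n_permutations
    )
    if use_exhaustive:
        rows = np.empty((n_distinct, n), dtype=np.intp)
        everyone = np.arange(n)
        for k, picked in enumerate(combinations(range(n), n_a)):
            a = np.asarray(picked, dtype=np.intp)
            rows[k, :n_a] = a
            rows[k, n_a:] = np.setdiff1d(everyone, a, assume_unique=True)
        return PermutationScheme(n_a, n_b, seed, rows, exhaustive=True)
    rng = np.random.default_rng(seed)
    rows = np.empty((n_permutations, n), dtype=np.intp)
    for k in range(n_permutations):
        rows[k] = rng.permutation(n)
    return PermutationScheme(n_a, n_b, seed, rows, exhaustive=False)


@dataclass
class EdgeTestResult:
    """Observed correlation differences with permutation p-values."""

    delta: np.ndarray  # region x region, group A - group B
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    region_ids: np.ndarray
    n_permutations: int
    scale: str = "r"

    @property
    def n_regions(self) -> int:
        return self.delta.shape[0]

    def to_edge_frame(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_regions, k=1)
        return pd.DataFrame(
            {
                "region_i": self.region_ids[i],
                "region_j": self.region_ids[j],
                "delta": self.delta[i, j],
                "p_uncorrected": self.p_uncorrected[i, j],
                "p_fwe": self.p_fwe[i, j],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)


def _group_delta(pooled: np.ndarray, idx_a, idx_b, scale: str) -> np.ndarray:
    ra = correlation_matrix(pooled[idx_a])
    rb = correlation_matrix(pooled[idx_b])
    if scale == "z":
        clip = 1.0 - 1e-15
        ra = np.arctanh(np.clip(ra, -clip, clip))
        rb = np.arctanh(np.clip(rb, -clip, clip))
        np.fill_diagonal(ra, 0.0)
        np.fill_diagonal(rb, 0.0)
    return ra - rb


def permute_edge_test(
    series_a: SubjectSeries,
    series_b: SubjectSeries,
    scheme: PermutationScheme,
    scale: str = "r",
) -> EdgeTestResult:
    """Edgewise two-tailed permutation test on the subtracted matrix.

    Parameters
    ----------
    scale : {"r", "z"}
        Compare raw correlation differences (default) or Fisher-z
        transformed differences.

    Notes
    -----
    A zero-variance column arising under a relabeling (possible only for
    pathological inputs) makes that permutation's statistic +inf on the
    affected edges — conservative, since it can only enlarge p-values' null
    counts — and is logged.
    """
    if not series_a.same_regions(series_b):
        raise ValueError("groups have different region sets or order")
    if scheme.n_a != series_a.n_subjects or scheme.n_b != series_b.n_subjects:
        raise ValueError("scheme was built for different group sizes")
    if scale not in ("r", "z"):
        raise ValueError("scale must be 'r' or 'z'")

    pooled = np.vstack([series_a.values, series_b.values])
    n_a = scheme.n_a
    n_regions = series_a.n_regions
    iu = np.triu_indices(n_regions, k=1)

    observed = _group_delta(pooled, np.arange(n_a), np.arange(n_a, scheme.n_pooled), scale)
    abs_obs = np.abs(observed[iu])

    n_perm = scheme.n_permutations
    count_ge = np.zeros(abs_obs.size, dtype=np.int64)
    max_stats = np.empty(n_perm)
    n_degenerate = 0
    for k in range(n_perm):
        idx = scheme.labelings[k]
        delta = _group_delta(pooled, idx[:n_a], idx[n_a:], scale)
        stat = np.abs(delta[iu])
        if np.isnan(stat).any():
            stat = np.where(np.isnan(stat), np.inf, stat)
            n_degenerate += 1
        count_ge += stat >= abs_obs - _TIE_TOL
        max_stats[k] = stat.max()
    if n_degenerate:
        logger.warning(
            "%d permutations produced zero-variance columns; their statistics "
            "were set to +inf (conservative)",
            n_degenerate,
        )

    p_unc_flat = (1.0 + count_ge) / (n_perm + 1.0)
    # FWE: count permutations whose max statistic reaches each observed edge.
    sorted_max = np.sort(max_stats)
    n_below = np.searchsorted(sorted_max, abs_obs - _TIE_TOL, side="left")
    p_fwe_flat = (1.0 + (n_perm - n_below)) / (n_perm + 1.0)

    def _to_matrix(flat: np.ndarray, diag: float) -> np.ndarray:
        m = np.full((n_regions, n_regions), diag)
        m[iu] = flat
        m[(iu[1], iu[0])] = flat
        return m

    return EdgeTestResult(
        delta=observed,
        p_uncorrected=_to_matrix(p_unc_flat, 1.0),
        p_fwe=_to_matrix(p_fwe_flat, 1.0),
        region_ids=series_a.region_ids,
        n_permutations=n_perm,
        scale=scale,
    )


@dataclass
class SignificantEdgeSet:
    """Edges passing a significance threshold, with per-region degrees."""

    edges: pd.DataFrame  # region_i, region_j, delta, p
    threshold: float
    correction: str
    degrees: pd.Series = field(default=None)  # significant-edge count per region

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def significant_edges(
    result: EdgeTestResult, alpha: float = 0.05, correction: str = "fwe"
) -> SignificantEdgeSet:
    """Select edges with p < alpha, sorted by |delta| descending.

    ``correction`` picks the familywise-corrected ("fwe") or per-edge
    uncorrected ("uncorrected") p-value; ties in |delta| break by canonical
    (i, j) index order.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if correction not in ("fwe", "uncorrected"):
        raise ValueError("correction must be 'fwe' or 'uncorrected'")
    frame = result.to_edge_frame()
    p = frame["p_fwe"] if correction == "fwe" else frame["p_uncorrected"]
    selected = frame[p < alpha].copy()
    selected["p"] = p[p < alpha]
    selected = selected.sort_values(
        by=["delta", "region_i", "region_j"],
        key=lambda c: -c.abs() if c.name == "delta" else c,
        kind="stable",
    ).reset_index(drop=True)
    degrees = pd.Series(0, index=result.region_ids, dtype=int)
    for col in ("region_i", "region_j"):
        counts = selected[col].value_counts()
        degrees.loc[counts.index] += counts.astype(int)
    return SignificantEdgeSet(
        edges=selected[["region_i", "region_j", "delta", "p"]],
        threshold=alpha,
        correction=correction,
        degrees=degrees,
    )
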