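"""Density sweeps: network parameters over a density grid and their tests.

Because proportional thresholding at a single density is arbitrary, network
parameters are evaluated over a grid of densities (the standard interval is
10-90% in 17 steps of 5%).  Small-worldness screening restricts comparisons
to the density levels where every compared group has sigma > 1, and group
differences in C and E are permutation-tested per level with the same
relabelings used for the edgewise test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import correlation_matrix, pearson_connectivity
from .graph import (
    ThresholdedGraph,
    network_metrics,
    small_worldness,
    threshold_adjacency,
)
from .permutation import PermutationScheme
from .series import SubjectSeries

__all__ = [
    "density_grid",
    "MetricProfile",
    "metric_profile",
    "small_world_validity_screen",
    "MetricComparison",
    "permute_metric_test",
    "permute_metric_tests",
]

logger = logging.getLogger(__name__)

#: metrics permute_metric_test understands
_METRICS = ("C", "E", "L")


def density_grid(low: float = 0.10, high: float = 0.90, step: float = 0.05) -> np.ndarray:
    """Inclusive density levels low, low+step, ..., high (4-decimal rounded).

    The standard grid (0.10, 0.90, 0.05) has exactly 17 levels.
    """
    if not (0 < low <= high <= 1):
        raise ValueError("need 0 < low <= high <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((high - low) / step + 1e-9)) + 1
    levels = np.round(low + step * np.arange(n_steps), 4)
    levels = levels[levels <= high + 1e-9]
    if levels.size == 0:
        raise ValueError("empty density grid")
    return levels


@dataclass
class MetricProfile:
    """Per-density network parameters and small-world profile of one group."""

    group_label: str
    table: pd.DataFrame  # density, C, E, L, gamma, lambda, sigma, ...

    def valid_densities(self, threshold: float = 1.0) -> np.ndarray:
        """Grid levels where sigma exceeds the small-world threshold."""
        mask = self.table["sigma"] > threshold
        return self.table.loc[mask, "density"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "group", self.group_label)
        out.to_csv(path, sep="\t", index=False)


def metric_profile(
    series: SubjectSeries,
    grid: np.ndarray,
    mode: str = "weighted",
    ranking: str = "signed",
    n_randomizations: int = 1000,
    seed: int = 0,
) -> MetricProfile:
    """Connectivity -> threshold -> C, E, L, gamma, lambda, sigma per density."""
    conn = pearson_connectivity(series)
    rng = np.random.default_rng(seed)
    rows = []
    for level in np.asarray(grid, dtype=float):
        graph = ThresholdedGraph(
            adjacency=threshold_adjacency(conn.values, level, mode=mode, ranking=ranking),
            density=level,
            mode=mode,
        )
        metrics = network_metrics(graph.adjacency, mode)
        sw = small_worldness(
            graph, n_randomizations=n_randomizations, seed=int(rng.integers(0, 2**31 - 1))
        )
        rows.append(
            {
                "density": level,
                "C": metrics.C,
                "E": metrics.E,
                "L": metrics.L,
                "unreachable_fraction": metrics.unreachable_fraction,
                "gamma": sw.gamma,
                "lambda": sw.lam,
                "sigma": sw.sigma,
            }
        )
    return MetricProfile(group_label=series.group_label, table=pd.DataFrame(rows))


def small_world_validity_screen(
    profiles: dict[str, MetricProfile] | list[MetricProfile],
    threshold: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-group densities with sigma > threshold, plus their intersection.

    The returned mapping carries one entry per group and an
    ``"intersection"`` entry — the analysis mask for group comparisons.
    Empty ranges are allowed and logged.
    """
    if isinstance(profiles, dict):
        items = list(profiles.items())
    else:
        items = [(p.group_label, p) for p in profiles]
    out: dict[str, np.ndarray] = {}
    common: set | None = None
    for label, profile in items:
        valid = profile.valid_densities(threshold)
        if valid.size == 0:
            logger.warning("group %s has no densities with sigma > %s", label, threshold)
        out[label] = valid
        common = set(valid) if common is None else common & set(valid)
    out["intersection"] = np.array(sorted(common or []))
    return out


@dataclass
class MetricComparison:
    """Per-density observed metric difference (A - B) with permutation p."""

    metric: str
    table: pd.DataFrame  # density, observed, p
    n_permutations: int
    group_a: str = ""
    group_b: str = ""

    def significant_ranges(self, alpha: float = 0.005) -> list[tuple[float, float]]:
        """Maximal runs of consecutive grid levels with p < alpha."""
        dens = self.table["density"].to_numpy()
        sig = (self.table["p"] < alpha).to_numpy()
        ranges: list[tuple[float, float]] = []
        start = None
        for level, flag in zip(dens, sig):
            if flag and start is None:
                start = level
            elif not flag and start is not None:
                ranges.append((start, prev))
                start = None
            prev = level
        if start is not None:
            ranges.append((start, dens[-1]))
        return ranges

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "metric", self.metric)
        out.to_csv(path, sep="\t", index=False)


def _metrics_at_levels(
    values: np.ndarray, levels: np.ndarray, mode: str, ranking: str
) -> dict[str, np.ndarray]:
    corr = correlation_matrix(values)
    out = {m: np.empty(levels.size) for m in _METRICS}
    for idx, level in enumerate(levels):
        adj = threshold_adjacency(corr, level, mode=mode, ranking=ranking)
        met = network_metrics(adj, mode)
        out["C"][idx] = met.C
        out["E"][idx] = met.E
        out["L"][idx] = met.L
    return out


def permute_metric_tests(
    series_a: SubjectSeries,
    series_b: SubjectSeries,
    grid: np.ndarray,
    scheme: PermutationScheme,
    metrics: tuple[str, ...] = ("C", "E"),
    mode: str = "weighted",
    ranking: str = "signed",
) -> dict[str, MetricComparison]:
    """Permutation tests of several network parameters in one pass.

    Reuses the relabelings of ``scheme`` (the same sets used by the edge
    test): at each density the observed difference of each parameter
    between groups A and B is compared with the differences across
    relabeled group pairs; p = (1 + #{|perm| >= |obs|}) / (n_perms + 1).
    All requested metrics share one sweep over the permutations.
    """
    for metric in metrics:
        if metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
    if not series_a.same_regions(series_b):
        raise ValueError("groups have different region sets or order")
    if scheme.n_a != series_a.n_subjects or scheme.n_b != series_b.n_subjects:
        raise ValueError("scheme was built for different group sizes")
    levels = np.asarray(grid, dtype=float)
    pooled = np.vstack([series_a.values, series_b.values])
    n_a = scheme.n_a

    obs_a = _metrics_at_levels(series_a.values, levels, mode, ranking)
    obs_b = _metrics_at_levels(series_b.values, levels, mode, ranking)
    observed = {m: obs_a[m] - obs_b[m] for m in metrics}
    abs_obs = {m: np.abs(observed[m]) for m in metrics}

    count_ge = {m: np.zeros(levels.size, dtype=np.int64) for m in metrics}
    for k in range(scheme.n_permutations):
        idx = scheme.labelings[k]
        ma = _metrics_at_levels(pooled[idx[:n_a]], levels, mode, ranking)
        mb = _metrics_at_levels(pooled[idx[n_a:]], levels, mode, ranking)
        for m in metrics:
            stat = np.abs(ma[m] - mb[m])
            stat = np.where(np.isnan(stat), np.inf, stat)
            # tie tolerance: relabelings reproducing the observed partition
            # must count even under row-order floating jitter
            count_ge[m] += stat >= abs_obs[m] - 1e-10

    out: dict[str, MetricComparison] = {}
    for m in metrics:
        p = (1.0 + count_ge[m]) / (scheme.n_permutations + 1.0)
        table = pd.DataFrame({"density": levels, "observed": observed[m], "p": p})
        out[m] = MetricComparison(
            metric=m,
            table=table,
            n_permutations=scheme.n_permutations,
            group_a=series_a.group_label,
            group_b=series_b.group_label,
        )
    return out


def permute_metric_test(
    series_a: SubjectSeries,
    series_b: SubjectSeries,
    grid: np.ndarray,
    scheme: PermutationScheme,
    metric: str = "C",
    mode: str = "weighted",
    ranking: str = "signed",
) -> MetricComparison:
    """Two-tailed permutation test of one network parameter per density."""
    return permute_metric_tests(
        series_a, series_b, grid, scheme, metrics=(metric,), mode=mode, ranking=ranking
    )[metric]
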