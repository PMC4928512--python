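"""Model-style front ends for the two group-comparison analyses.

`EdgeComparison` and `NetworkComparison` wrap the permutation machinery the
way fitted models wrap estimators: construct from two subject-series
tables, call :meth:`fit`, and receive a Results object carrying the
estimates (correlation or parameter differences), their permutation
p-values, diagnostics and a ``summary()`` table.  Both models can share one
:class:`~metabnet.permutation.PermutationScheme` so the edgewise and
network-parameter tests use identical relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, pearson_connectivity
from .permutation import (
    EdgeTestResult,
    PermutationScheme,
    SignificantEdgeSet,
    make_scheme,
    permute_edge_test,
    significant_edges,
)
from .series import SubjectSeries
from .sweep import (
    MetricComparison,
    MetricProfile,
    density_grid,
    metric_profile,
    permute_metric_tests,
    small_world_validity_screen,
)

__all__ = [
    "EdgeComparison",
    "EdgeComparisonResults",
    "NetworkComparison",
    "NetworkComparisonResults",
]


def _series_from_frame(frame: pd.DataFrame, label: str) -> SubjectSeries:
    if "subject_id" in frame.columns:
        frame = frame.set_index("subject_id")
    return SubjectSeries(data=frame, group_label=label)


class EdgeComparison:
    """Edgewise metabolic-connectivity comparison between two groups.

    Tests every interregional correlation difference (group A - group B)
    against a subject-relabeling permutation null, with max-statistic
    familywise control.

    Parameters
    ----------
    series_a, series_b : SubjectSeries
        Subjects x regions uptake tables with identical region order.
    scale : {"r", "z"}
        Compare raw correlation differences (default) or Fisher-z values.
    """

    def __init__(self, series_a: SubjectSeries, series_b: SubjectSeries, scale: str = "r"):
        if not series_a.same_regions(series_b):
            raise ValueError("groups have different region sets or order")
        self.series_a = series_a
        self.series_b = series_b
        self.scale = scale

    @classmethod
    def from_dataframes(
        cls,
        frame_a: pd.DataFrame,
        frame_b: pd.DataFrame,
        labels: tuple[str, str] = ("A", "B"),
        scale: str = "r",
    ) -> "EdgeComparison":
        return cls(
            _series_from_frame(frame_a, labels[0]),
            _series_from_frame(frame_b, labels[1]),
            scale=scale,
        )

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int = 0,
        scheme: PermutationScheme | None = None,
    ) -> "EdgeComparisonResults":
        """Run the permutation test and return the results object."""
        if scheme is None:
            scheme = make_scheme(
                self.series_a.n_subjects, self.series_b.n_subjects, n_permutations, seed
            )
        result = permute_edge_test(self.series_a, self.series_b, scheme, scale=self.scale)
        return EdgeComparisonResults(
            model=self,
            result=result,
            scheme=scheme,
            connectivity_a=pearson_connectivity(self.series_a),
            connectivity_b=pearson_connectivity(self.series_b),
        )


@dataclass
class EdgeComparisonResults:
    """Fitted edgewise comparison: deltas, p-values, significant edges."""

    model: EdgeComparison
    result: EdgeTestResult
    scheme: PermutationScheme
    connectivity_a: ConnectivityMatrix
    connectivity_b: ConnectivityMatrix

    @property
    def delta(self) -> np.ndarray:
        return self.result.delta

    @property
    def p_uncorrected(self) -> np.ndarray:
        return self.result.p_uncorrected

    @property
    def p_fwe(self) -> np.ndarray:
        return self.result.p_fwe

    def significant_edges(
        self, alpha: float = 0.05, correction: str = "fwe"
    ) -> SignificantEdgeSet:
        return significant_edges(self.result, alpha=alpha, correction=correction)

    def region_uptake_difference(self) -> pd.Series:
        """Per-region difference of mean uptake (A - B), for node coloring."""
        return self.model.series_a.region_means() - self.model.series_b.region_means()

    def summary(self, alpha: float = 0.05, correction: str = "fwe", max_rows: int = 20) -> str:
        sig = self.significant_edges(alpha, correction)
        a, b = self.model.series_a, self.model.series_b
        lines = [
            "Edgewise metabolic connectivity comparison",
            "=" * 58,
            f"groups:          {a.group_label} (n={a.n_subjects}) vs "
            f"{b.group_label} (n={b.n_subjects})",
            f"regions/edges:   {a.n_regions} / {self.result.delta.shape[0] * (self.result.delta.shape[0] - 1) // 2}",
            f"permutations:    {self.scheme.n_permutations}"
            + ("  (exhaustive)" if self.scheme.exhaustive else ""),
            f"scale:           {'Fisher z' if self.result.scale == 'z' else 'raw correlation'}",
            f"threshold:       p < {alpha} ({correction})",
            f"significant:     {sig.n_edges} edges",
            "-" * 58,
        ]
        if sig.n_edges:
            head = sig.edges.head(max_rows).to_string(index=False, float_format=lambda v: f"{v: .4f}")
            lines.append(head)
            if sig.n_edges > max_rows:
                lines.append(f"... {sig.n_edges - max_rows} more edges")
        else:
            lines.append("(no significant edges)")
        return "\n".join(lines)


class NetworkComparison:
    """Density-swept network-parameter comparison between two groups.

    Sweeps clustering coefficient and global efficiency over a proportional
    density grid, screens densities for small-worldness (sigma > 1 in both
    groups), and permutation-tests the per-density group differences using
    the same relabelings as the edgewise test.
    """

    def __init__(
        self,
        series_a: SubjectSeries,
        series_b: SubjectSeries,
        grid: np.ndarray | None = None,
        mode: str = "weighted",
        ranking: str = "signed",
        metrics: tuple[str, ...] = ("C", "E"),
    ):
        if not series_a.same_regions(series_b):
            raise ValueError("groups have different region sets or order")
        self.series_a = series_a
        self.series_b = series_b
        self.grid = density_grid() if grid is None else np.asarray(grid, dtype=float)
        self.mode = mode
        self.ranking = ranking
        self.metrics = metrics

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int = 0,
        scheme: PermutationScheme | None = None,
        n_randomizations: int = 100,
        sigma_threshold: float = 1.0,
    ) -> "NetworkComparisonResults":
        """Profile both groups, screen densities, test the differences.

        ``n_randomizations`` sets the rewired-null count behind each
        group's small-world profile (the full-analysis default of 1000 is
        configurable; 100 keeps the screen affordable inside sweeps).
        """
        if scheme is None:
            scheme = make_scheme(
                self.series_a.n_subjects, self.series_b.n_subjects, n_permutations, seed
            )
        rng = np.random.default_rng(seed)
        profiles = {
            s.group_label
            or name: metric_profile(
                s,
                self.grid,
                mode=self.mode,
                ranking=self.ranking,
                n_randomizations=n_randomizations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for name, s in (("A", self.series_a), ("B", self.series_b))
        }
        validity = small_world_validity_screen(profiles, threshold=sigma_threshold)
        comparisons = permute_metric_tests(
            self.series_a,
            self.series_b,
            self.grid,
            scheme,
            metrics=self.metrics,
            mode=self.mode,
            ranking=self.ranking,
        )
        return NetworkComparisonResults(
            model=self,
            profiles=profiles,
            validity=validity,
            comparisons=comparisons,
            scheme=scheme,
        )


@dataclass
class NetworkComparisonResults:
    """Fitted density sweep: per-group profiles and per-density tests."""

    model: NetworkComparison
    profiles: dict[str, MetricProfile]
    validity: dict[str, np.ndarray]
    comparisons: dict[str, MetricComparison]
    scheme: PermutationScheme

    def significant_ranges(self, metric: str, alpha: float = 0.005) -> list[tuple[float, float]]:
        return self.comparisons[metric].significant_ranges(alpha)

    def comparison_table(self) -> pd.DataFrame:
        """Tidy per-density table of observed differences and p-values."""
        frames = []
        for metric, comp in self.comparisons.items():
            t = comp.table.copy()
            t.insert(0, "metric", metric)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def summary(self, alpha: float = 0.005) -> str:
        a, b = self.model.series_a, self.model.series_b
        inter = self.validity.get("intersection", np.array([]))
        lines = [
            "Network-parameter comparison over the density grid",
            "=" * 58,
            f"groups:        {a.group_label} (n={a.n_subjects}) vs "
            f"{b.group_label} (n={b.n_subjects})",
            f"grid:          {self.model.grid[0]:.2f}-{self.model.grid[-1]:.2f} "
            f"({self.model.grid.size} levels), mode={self.model.mode}",
            f"permutations:  {self.scheme.n_permutations}",
            "small-world screen (sigma > 1):",
        ]
        for label, levels in self.validity.items():
            if label == "intersection":
                continue
            lines.append(f"  {label:<12} {_fmt_levels(levels)}")
        lines.append(f"  {'shared':<12} {_fmt_levels(inter)}")
        lines.append("-" * 58)
        for metric, comp in self.comparisons.items():
            ranges = comp.significant_ranges(alpha)
            txt = ", ".join(f"{lo:.0%}-{hi:.0%}" for lo, hi in ranges) or "none"
            lines.append(f"{metric}: significant density ranges at p < {alpha}: {txt}")
        table = self.comparison_table()
        lines.append(
            table.to_string(index=False, float_format=lambda v: f"{v: .4f}")
        )
        return "\n".join(lines)


def _fmt_levels(levels: np.ndarray) -> str:
    levels = np.asarray(levels)
    if levels.size == 0:
        return "(empty)"
    return f"{levels[0]:.0%}-{levels[-1]:.0%} ({levels.size} levels)"
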