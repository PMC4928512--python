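"""Synthetic cohorts with controlled correlation structure.

The study-style data — per-group subjects x regions tables of normalized
FDG uptake — are not publicly deposited, so this module generates them:
subjects are drawn from a multivariate normal whose correlation matrix has
a modular (lobe-like) block structure, with optional planted overrides on
specific region pairs and a global within-module attenuation that mimics
disease-related network weakening.  Everything is seed-deterministic.

Default cohort sizes follow the study design this package emulates:
74 early-onset patients vs 20 young controls and 46 late-onset patients vs
13 old controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .atlas import RegionAtlas
from .series import SubjectSeries
from .volumes import IntensityVolume

__all__ = [
    "ModularCovariance",
    "CohortSpec",
    "PlantedEffect",
    "build_covariance",
    "simulate_group",
    "simulate_cohort_pair",
    "simulate_phantom_volume",
    "default_cohort_spec",
    "default_modules",
    "default_planted_edges",
    "ring_lattice_graph",
    "random_graph",
]

#: group sizes of the emulated study design
DEFAULT_GROUP_SIZES = {"EAD": 74, "young": 20, "LAD": 46, "old": 13}


@dataclass
class ModularCovariance:
    """Blueprint for a modular correlation matrix.

    ``module_of`` assigns each region to a module (lobe-like label); pairs
    within a module correlate at ``within_r``, pairs across modules at
    ``between_r``; ``planted_edges`` lists (i, j, r) overrides applied
    before the positive-semidefinite repair.
    """

    n_regions: int
    module_of: np.ndarray
    within_r: float = 0.75
    between_r: float = 0.45
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.module_of = np.asarray(self.module_of, dtype=int)
        if self.module_of.size != self.n_regions:
            raise ValueError("module assignment must cover all regions")
        for r in (self.within_r, self.between_r):
            if not -1 < r < 1:
                raise ValueError("block correlations must satisfy |r| < 1")
        for i, j, r in self.planted_edges:
            if not -1 < r < 1:
                raise ValueError("planted correlations must satisfy |r| < 1")
            if i == j:
                raise ValueError("planted edges must be off-diagonal")

    def attenuated(self, factor: float) -> "ModularCovariance":
        """Scale the within-module excess correlation by (1 - factor).

        factor = 0 leaves the structure unchanged; factor = 1 flattens the
        modules down to the between-module level.
        """
        if not 0 <= factor <= 1:
            raise ValueError("attenuation factor must be in [0, 1]")
        new_within = self.between_r + (self.within_r - self.between_r) * (1 - factor)
        return ModularCovariance(
            n_regions=self.n_regions,
            module_of=self.module_of,
            within_r=new_within,
            between_r=self.between_r,
            planted_edges=list(self.planted_edges),
        )


def build_covariance(spec: ModularCovariance, max_repair_drift: float = 0.1) -> np.ndarray:
    """Materialize a valid correlation matrix from a modular blueprint.

    Block structure first, then planted overrides, then a nearest-PSD
    repair by eigenvalue clipping (floor 1e-8) with the diagonal rescaled
    back to 1.  If the repair moves any entry by more than
    ``max_repair_drift`` the requested structure is infeasible.
    """
    same = spec.module_of[:, None] == spec.module_of[None, :]
    target = np.where(same, spec.within_r, spec.between_r).astype(float)
    np.fill_diagonal(target, 1.0)
    for i, j, r in spec.planted_edges:
        target[i, j] = target[j, i] = r

    eigval, eigvec = np.linalg.eigh(target)
    if eigval.min() >= 1e-8:
        return target
    clipped = np.clip(eigval, 1e-8, None)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    drift = np.abs(repaired - target).max()
    if drift > max_repair_drift:
        raise ValueError(
            f"infeasible structure: PSD repair moved an entry by {drift:.3f}"
        )
    return repaired


def simulate_group(
    n_subjects: int,
    covariance: np.ndarray,
    means: np.ndarray | float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    region_ids=None,
    group_label: str = "",
) -> SubjectSeries:
    """Draw a subjects x regions table from a multivariate normal.

    ``covariance`` is a correlation matrix; subject rows are independent
    draws of mean ``means`` and per-region SD ``noise_sd`` with that
    correlation structure.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    cov = np.asarray(covariance, dtype=float)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-8:
        raise ValueError("covariance is not positive semidefinite")
    root = eigvec * np.sqrt(np.clip(eigval, 0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, cov.shape[0]))
    values = np.asarray(means, dtype=float) + noise_sd * (z @ root.T)
    return SubjectSeries.from_array(
        values, region_ids=region_ids, group_label=group_label
    )


def default_modules(n_regions: int = 90, n_modules: int = 6) -> np.ndarray:
    """Contiguous, near-equal module assignment (coarse lobe stand-ins)."""
    return (np.arange(n_regions) * n_modules // n_regions).astype(int)


@dataclass
class PlantedEffect:
    """Between-group difference planted into the case group.

    ``edges`` lists region-index pairs whose correlation drops from
    ``r_control`` to ``r_case`` in the case group; ``global_attenuation``
    additionally weakens the whole case covariance, scaling every
    off-diagonal correlation by (1 - a) — a diffuse loss of metabolic
    coupling.  Module-restricted flattening is available separately via
    :meth:`ModularCovariance.attenuated`.
    """

    edges: list[tuple[int, int]] = field(default_factory=list)
    r_control: float = 0.6
    r_case: float = 0.1
    global_attenuation: float = 0.0


@dataclass
class CohortSpec:
    """Full recipe for a pair of comparable synthetic cohorts."""

    n_case: int = 74
    n_control: int = 20
    base: ModularCovariance = None
    effect: PlantedEffect = None
    means: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0
    case_label: str = "EAD"
    control_label: str = "young"

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["base"]["module_of"] = self.base.module_of.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)


def default_planted_edges(
    module_of: np.ndarray, module_a: int = 1, module_b: int = 4, n_edges: int = 10
) -> list[tuple[int, int]]:
    """Deterministic cross-module region pairs for planting an effect.

    Pairs one module's regions with another's, each region used at most
    once (disjoint pairs keep the planted structure positive-semidefinite
    friendly).  The two default modules play the role of the "cingulate"
    and "occipital" blocks; the names are labels only, not anatomical
    claims.
    """
    a_regions = np.flatnonzero(module_of == module_a)
    b_regions = np.flatnonzero(module_of == module_b)
    n_avail = min(a_regions.size, b_regions.size)
    edges = [
        (min(int(a_regions[k]), int(b_regions[k])), max(int(a_regions[k]), int(b_regions[k])))
        for k in range(min(n_edges, n_avail))
    ]
    if len(edges) < n_edges:  # tiny modules: fill with remaining combinations
        for i in a_regions:
            for j in b_regions:
                pair = (min(int(i), int(j)), max(int(i), int(j)))
                if pair not in edges:
                    edges.append(pair)
                if len(edges) == n_edges:
                    break
            if len(edges) == n_edges:
                break
    return edges[:n_edges]


def default_cohort_spec(
    n_regions: int = 90,
    n_case: int = 74,
    n_control: int = 20,
    seed: int = 0,
) -> CohortSpec:
    """The default synthetic study: EAD-like cohort vs young-control-like.

    Ten cross-module edges drop from r = 0.6 to r = 0.1 in the case group
    on top of a modular background (6 modules, within-module r = 0.75,
    between-module r = 0.45).
    """
    modules = default_modules(n_regions)
    effect = PlantedEffect(edges=default_planted_edges(modules))
    base = ModularCovariance(
        n_regions=n_regions,
        module_of=modules,
        planted_edges=[(i, j, effect.r_control) for i, j in effect.edges],
    )
    return CohortSpec(
        n_case=n_case, n_control=n_control, base=base, effect=effect, seed=seed
    )


def simulate_cohort_pair(
    spec: CohortSpec, effect: PlantedEffect | None = None
) -> tuple[SubjectSeries, SubjectSeries]:
    """Simulate (case, control) groups with a planted difference.

    The control group follows the base covariance with the planted edges at
    ``r_control``; the case group has them at ``r_case`` and, optionally,
    globally attenuated modules.  With a zero effect both groups share one
    covariance.
    """
    effect = effect if effect is not None else spec.effect
    if effect is None:
        effect = PlantedEffect()
    control_cov_spec = ModularCovariance(
        n_regions=spec.base.n_regions,
        module_of=spec.base.module_of,
        within_r=spec.base.within_r,
        between_r=spec.base.between_r,
        planted_edges=[(i, j, effect.r_control) for i, j in effect.edges],
    )
    case_cov_spec = ModularCovariance(
        n_regions=spec.base.n_regions,
        module_of=spec.base.module_of,
        within_r=spec.base.within_r,
        between_r=spec.base.between_r,
        planted_edges=[(i, j, effect.r_case) for i, j in effect.edges],
    )
    control_cov = build_covariance(control_cov_spec)
    case_cov = build_covariance(case_cov_spec)
    if effect.global_attenuation:
        a = effect.global_attenuation
        if not 0 <= a <= 1:
            raise ValueError("global attenuation must be in [0, 1]")
        # convex combination with the identity keeps the matrix PSD
        case_cov = np.eye(case_cov.shape[0]) + (1 - a) * (case_cov - np.eye(case_cov.shape[0]))
    rng = np.random.default_rng(spec.seed)
    seed_case = int(rng.integers(0, 2**31 - 1))
    seed_control = int(rng.integers(0, 2**31 - 1))
    case = simulate_group(
        spec.n_case, case_cov, spec.means, spec.noise_sd, seed_case,
        group_label=spec.case_label,
    )
    control = simulate_group(
        spec.n_control, control_cov, spec.means, spec.noise_sd, seed_control,
        group_label=spec.control_label,
    )
    return case, control


def ring_lattice_graph(
    n_nodes: int = 50, degree: int = 6, rewire_p: float = 0.05, seed: int = 0
):
    """Watts-Strogatz-style ring lattice as a binary thresholded graph.

    Each node connects to its ``degree`` nearest ring neighbours; each edge
    is rewired to a uniform random non-duplicate endpoint with probability
    ``rewire_p``.  The classic small-world construction: high clustering,
    short paths, sigma > 1 against degree-preserving nulls.
    """
    from .graph import ThresholdedGraph

    if degree % 2 or degree >= n_nodes:
        raise ValueError("degree must be even and below n_nodes")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=float)
    for offset in range(1, degree // 2 + 1):
        for i in range(n_nodes):
            j = (i + offset) % n_nodes
            adj[i, j] = adj[j, i] = 1.0
    edges = np.column_stack(np.nonzero(np.triu(adj, k=1)))
    for i, j in edges:
        if rng.random() < rewire_p:
            candidates = np.flatnonzero((adj[i] == 0) & (np.arange(n_nodes) != i))
            if candidates.size:
                k = int(rng.choice(candidates))
                adj[i, j] = adj[j, i] = 0.0
                adj[i, k] = adj[k, i] = 1.0
    m = n_nodes * (n_nodes - 1) // 2
    n_edges = int(np.count_nonzero(np.triu(adj, k=1)))
    return ThresholdedGraph(adjacency=adj, density=n_edges / m, mode="binary")


def random_graph(n_nodes: int = 50, p: float = 0.3, seed: int = 0):
    """Erdos-Renyi G(n, p) as a binary thresholded graph."""
    from .graph import ThresholdedGraph

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu[0].size) < p
    adj = np.zeros((n_nodes, n_nodes), dtype=float)
    adj[iu[0][mask], iu[1][mask]] = 1.0
    adj += adj.T
    m = n_nodes * (n_nodes - 1) // 2
    return ThresholdedGraph(adjacency=adj, density=int(mask.sum()) / m, mode="binary")


def simulate_phantom_volume(
    atlas: RegionAtlas,
    region_means: dict[int, float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityVolume:
    """Toy phantom: each voxel is its region's mean plus Gaussian noise.

    Exercises the ROI front end (smoothing, cerebellar normalization, mean
    extraction) on a label volume with known ground truth; background
    voxels are zero.
    """
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume")
    codes = atlas.codes
    if isinstance(region_means, dict):
        missing = [int(c) for c in codes if int(c) not in region_means]
        if missing:
            raise ValueError(f"missing region mean(s) for codes {missing}")
        mean_by_code = {int(c): float(region_means[int(c)]) for c in codes}
    else:
        region_means = np.asarray(region_means, dtype=float)
        if region_means.size != codes.size:
            raise ValueError("means must cover all atlas regions")
        mean_by_code = {int(c): float(m) for c, m in zip(codes, region_means)}
    rng = np.random.default_rng(seed)
    vol = np.zeros(atlas.label_volume.shape, dtype=float)
    for code, mean in mean_by_code.items():
        mask = atlas.label_volume == code
        vol[mask] = mean
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=vol.shape)
        vol = np.where(atlas.label_volume > 0, vol + noise, 0.0)
    return IntensityVolume(voxels=vol, affine=atlas.affine)
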