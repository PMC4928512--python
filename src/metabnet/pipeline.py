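"""Config-driven pipeline: load groups, compare, export viewer-ready files.

The pipeline composes the full analysis from a YAML/JSON config: read
subject x region tables (or reduce registered NIfTI volumes through the ROI
front end), build per-group connectivity matrices, run the edgewise and
network-parameter permutation comparisons for each configured pair, and
write TSV/JSON artifacts plus BrainNet-style .node/.edge text files.  Every
output directory carries a run log with the config hash, seeds and stage
wall times, so a rerun with the same config reproduces the numbers
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .atlas import RegionAtlas, load_aal_centroids, load_aal_table, load_label_table
from .models import EdgeComparison, NetworkComparison
from .permutation import SignificantEdgeSet, make_scheme
from .series import SubjectSeries
from .sweep import density_grid
from .volumes import IntensityVolume, build_subject_series

__all__ = ["PipelineConfig", "run_pipeline", "export_brainnet"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable and hashable.

    ``groups`` maps group label to a subject-series TSV (``input_mode
    "tables"``) or to a list of NIfTI paths (``input_mode "volumes"``);
    ``comparisons`` lists [case, control] label pairs.
    """

    groups: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    input_mode: str = "tables"
    atlas_labels: str | None = None  # None -> packaged AAL table
    atlas_volume: str | None = None
    smoothing_fwhm_mm: float | None = None  # None -> off (precomputed tables)
    n_permutations: int = 10_000
    n_randomizations: int = 100
    seed: int = 0
    density_low: float = 0.10
    density_high: float = 0.90
    density_step: float = 0.05
    mode: str = "weighted"
    ranking: str = "signed"
    scale: str = "r"
    alpha: float = 0.05
    correction: str = "fwe"
    metric_alpha: float = 0.005
    output_dir: str = "metabnet_output"

    def __post_init__(self) -> None:
        if self.input_mode not in ("tables", "volumes"):
            raise ValueError("input_mode must be 'tables' or 'volumes'")
        labels = set(self.groups)
        for pair in self.comparisons:
            if len(pair) != 2:
                raise ValueError("each comparison must name exactly two groups")
            missing = set(pair) - labels
            if missing:
                raise ValueError(f"comparison references unknown group(s): {missing}")

    def validate_paths(self) -> None:
        paths = []
        for value in self.groups.values():
            paths.extend(value if isinstance(value, (list, tuple)) else [value])
        for name in ("atlas_labels", "atlas_volume"):
            if getattr(self, name):
                paths.append(getattr(self, name))
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        raw = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()[:12]


def _load_groups(config: PipelineConfig) -> dict[str, SubjectSeries]:
    if config.input_mode == "tables":
        return {
            label: SubjectSeries.from_tsv(path, group_label=label)
            for label, path in config.groups.items()
        }
    # volumes: build series through the ROI front end
    table = (
        load_label_table(config.atlas_labels) if config.atlas_labels else load_aal_table()
    )
    if not config.atlas_volume:
        raise ValueError("volume input requires an atlas label volume")
    atlas_vol = IntensityVolume.from_nifti(config.atlas_volume)
    atlas = RegionAtlas(
        label_table=table,
        label_volume=atlas_vol.voxels.astype(int),
        affine=atlas_vol.affine,
    )
    groups = {}
    for label, paths in config.groups.items():
        volumes = [IntensityVolume.from_nifti(p) for p in paths]
        groups[label] = build_subject_series(
            volumes,
            atlas,
            group_label=label,
            smooth_fwhm_mm=config.smoothing_fwhm_mm,
            normalize=True,
            drop_cerebellar=True,
        )
    return groups


def export_brainnet(
    edges: SignificantEdgeSet,
    node_coords: pd.DataFrame,
    node_values: pd.Series,
    region_ids: np.ndarray,
    prefix: str | Path,
    labels: dict[int, str] | None = None,
) -> tuple[Path, Path]:
    """Write BrainNet-style .node and .edge text files for an edge set.

    The .node file columns are x, y, z, color value (per-region metabolic
    level difference), size value (significant-edge degree) and label; the
    .edge file is the N x N signed difference matrix masked to the
    significant edges.  Every region must have a coordinate row.
    """
    coords = node_coords.set_index("code") if "code" in node_coords.columns else node_coords
    missing = [int(c) for c in region_ids if int(c) not in coords.index]
    if missing:
        raise ValueError(f"missing coordinates for region code(s): {missing[:5]}")
    prefix = Path(prefix)
    node_path = prefix.with_suffix(".node")
    edge_path = prefix.with_suffix(".edge")

    id_to_pos = {int(c): k for k, c in enumerate(region_ids)}
    n = len(region_ids)
    matrix = np.zeros((n, n))
    for row in edges.edges.itertuples(index=False):
        i, j = id_to_pos[int(row.region_i)], id_to_pos[int(row.region_j)]
        matrix[i, j] = matrix[j, i] = row.delta

    with open(node_path, "w") as fh:
        for code in region_ids:
            code = int(code)
            x, y, z = coords.loc[code, ["x", "y", "z"]]
            color = float(node_values.get(code, 0.0))
            size = int(edges.degrees.get(code, 0)) if edges.degrees is not None else 0
            label = (labels or {}).get(code) or (
                coords.loc[code, "name"] if "name" in coords.columns else f"r{code}"
            )
            fh.write(f"{x:.1f}\t{y:.1f}\t{z:.1f}\t{color:.6f}\t{size}\t{label}\n")
    np.savetxt(edge_path, matrix, fmt="%.6f", delimiter="\t")
    return node_path, edge_path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis end to end; returns the output index.

    Artifacts per run: per-group connectivity matrices and metric profiles,
    per-pair edge tests, significant-edge sets, BrainNet exports and
    network-parameter comparisons, plus ``run_log.json``.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    index: dict = {"config_hash": config.digest(), "outputs": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                value = fn()
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})
            return value

        return wrap

    config.validate_paths()
    groups = stage("load_groups")(lambda: _load_groups(config))

    grid = density_grid(config.density_low, config.density_high, config.density_step)
    centroids = load_aal_centroids()
    names = {int(r.code): r.name for r in load_aal_table().itertuples(index=False)}

    def connectivity_stage():
        paths = {}
        for label, series in groups.items():
            from .connectivity import pearson_connectivity

            path = out / f"connectivity_{label}.tsv"
            pearson_connectivity(series).to_tsv(path)
            paths[label] = str(path)
        return paths

    index["outputs"]["connectivity"] = stage("connectivity")(connectivity_stage)

    rng = np.random.default_rng(config.seed)
    for label_a, label_b in config.comparisons:
        pair = f"{label_a}_vs_{label_b}"
        series_a, series_b = groups[label_a], groups[label_b]
        pair_seed = int(rng.integers(0, 2**31 - 1))
        scheme = make_scheme(
            series_a.n_subjects, series_b.n_subjects, config.n_permutations, pair_seed
        )

        def edge_stage():
            model = EdgeComparison(series_a, series_b, scale=config.scale)
            fitted = model.fit(scheme=scheme)
            fitted.result.to_tsv(out / f"edges_{pair}.tsv")
            sig = fitted.significant_edges(config.alpha, config.correction)
            sig.edges.to_csv(out / f"significant_edges_{pair}.tsv", sep="\t", index=False)
            node_path, edge_path = export_brainnet(
                sig,
                centroids,
                fitted.region_uptake_difference(),
                series_a.region_ids,
                out / f"brainnet_{pair}",
                labels=names,
            )
            with open(out / f"summary_edges_{pair}.txt", "w") as fh:
                fh.write(fitted.summary(config.alpha, config.correction))
            return {
                "edges": str(out / f"edges_{pair}.tsv"),
                "significant": str(out / f"significant_edges_{pair}.tsv"),
                "node": str(node_path),
                "edge": str(edge_path),
                "n_significant": sig.n_edges,
            }

        index["outputs"][f"edge_test_{pair}"] = stage(f"edge_test_{pair}")(edge_stage)

        def network_stage():
            model = NetworkComparison(
                series_a, series_b, grid=grid, mode=config.mode, ranking=config.ranking
            )
            fitted = model.fit(
                scheme=scheme,
                seed=pair_seed,
                n_randomizations=config.n_randomizations,
            )
            for label, profile in fitted.profiles.items():
                profile.to_tsv(out / f"profile_{pair}_{label}.tsv")
            fitted.comparison_table().to_csv(
                out / f"network_comparison_{pair}.tsv", sep="\t", index=False
            )
            ranges = {
                metric: fitted.significant_ranges(metric, config.metric_alpha)
                for metric in fitted.comparisons
            }
            payload = {
                "alpha": config.metric_alpha,
                "significant_ranges": ranges,
                "validity": {k: list(map(float, v)) for k, v in fitted.validity.items()},
            }
            with open(out / f"network_ranges_{pair}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            with open(out / f"summary_network_{pair}.txt", "w") as fh:
                fh.write(fitted.summary(config.metric_alpha))
            return {
                "comparison": str(out / f"network_comparison_{pair}.tsv"),
                "ranges": str(out / f"network_ranges_{pair}.json"),
            }

        index["outputs"][f"network_{pair}"] = stage(f"network_{pair}")(network_stage)

    log = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stages": stages,
        "total_seconds": round(time.time() - t_start, 3),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    index["run_log"] = str(out / "run_log.json")
    return index
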