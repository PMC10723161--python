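"""Configuration-driven end-to-end runs and report generation.

``run_pipeline`` executes simulate -> preprocess -> connectivity (per seed
network, static and windowed) -> three-group voxelwise statistics with GRF
cluster correction -> post hoc pairwise tests -> FC-cognition correlations,
and writes TSV reports plus a provenance record.  Subjects are streamed:
only one 4D image is in memory at a time.

This package is a library; the functions here (plus the scripts in
``examples/``) are the command surface — there is no shell CLI.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import demographics_table, fc_cognition_correlations
from .connectivity import (
    DEFAULT_SEEDS,
    WindowScheme,
    dynamic_cv_map,
    make_sphere_seed,
    smooth_volume,
    static_fc_map,
)
from .preprocess import preprocess_bold
from .rft import (
    ClusterResult,
    build_design,
    estimate_smoothness,
    extract_cluster_values,
    grf_cluster_threshold,
    posthoc_pairwise,
    voxelwise_ancova,
)
from .simulate import SimScene, generate_participants, iter_cohort, tissue_masks

CLUSTER_REPORT_COLUMNS = [
    "brain_network", "anatomical_region", "number_of_voxels",
    "peak_mni_x", "peak_mni_y", "peak_mni_z", "peak_intensity",
]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    Thresholds follow the study design: cluster-forming voxel p < 0.001
    with GRF cluster p < 0.05, Bonferroni post hoc at 0.01, and a
    Bonferroni-corrected 0.01 level for FC-cognition correlations.
    """

    scene: SimScene
    out_dir: str | Path
    n_per_group: tuple[int, int, int] = (15, 15, 15)
    networks: tuple[str, ...] = ("DMN",)
    window_schemes: tuple[tuple[int, int], ...] = ((50, 2),)
    variability_kind: str = "cv"
    smooth_fwhm_mm: float = 6.0
    smooth_static: bool = True
    n_drop: int = 10
    band_hz: tuple[float, float] = (0.01, 0.1)
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    posthoc_alphas: tuple[float, float] = (0.05, 0.01)
    bonferroni_alpha: float = 0.01
    rng_seed: int = 0
    map_dtype: str = "float32"

    def __post_init__(self) -> None:
        for p in (self.voxel_p, self.cluster_p, self.bonferroni_alpha):
            if not 0 < p < 1:
                raise ValueError("probability thresholds must lie in (0, 1)")
        for length, _ in self.window_schemes:
            self.scene.check_supports_windows(length, self.n_drop)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["scene"]["regions"] = [list(map(str, r.values())) for r in doc["scene"]["regions"]]
        doc["out_dir"] = None  # location must not change the hash
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SubjectMaps:
    """Per-subject smoothed maps stacked over the cohort."""

    static: dict[str, np.ndarray]                    # network -> (n, *grid)
    dynamic: dict[tuple[str, tuple[int, int]], np.ndarray]
    table: pd.DataFrame
    masks: dict[str, np.ndarray]


def compute_subject_maps(
    table: pd.DataFrame,
    scene: SimScene,
    config: RunConfig,
    kinds: tuple[str, ...] = ("static", "dynamic"),
    progress=None,
) -> SubjectMaps:
    """Simulate + preprocess each subject once and compute every requested
    seed map (static and per window scheme), streaming over subjects."""
    masks = tissue_masks(scene)
    gm = masks["gm"]
    brain = masks["brain"]
    aff = scene.affine
    seeds = {s.network: s for s in DEFAULT_SEEDS if s.network in config.networks}
    seed_masks = {
        net: make_sphere_seed(spec, aff, tuple(scene.grid_shape))
        for net, spec in seeds.items()
    }
    schemes = [WindowScheme(length, step) for length, step in config.window_schemes]
    n = len(table)
    grid = tuple(scene.grid_shape)
    static = {net: np.zeros((n,) + grid) for net in seeds if "static" in kinds}
    dynamic = {
        (net, (sch.length_tr, sch.step_tr)): np.zeros((n,) + grid)
        for net in seeds
        for sch in schemes
        if "dynamic" in kinds
    }
    vox = np.full(3, scene.voxel_size)
    dtype = np.float32 if config.map_dtype == "float32" else np.float64
    table = table.copy().reset_index(drop=True)
    for i, (rec, img, motion) in enumerate(iter_cohort(table, scene, dtype=dtype)):
        table.loc[i, "mean_fd"] = rec["mean_fd"]
        clean, _ = preprocess_bold(
            img, motion, masks["wm"], masks["csf"],
            n_drop=config.n_drop, band_hz=config.band_hz, mask=brain,
        )
        for net, spec in seeds.items():
            if "static" in kinds:
                zmap = static_fc_map(clean, seed_masks[net], gm, seed=spec)
                vals = zmap.values
                if config.smooth_static and config.smooth_fwhm_mm > 0:
                    vals = smooth_volume(vals, vox, config.smooth_fwhm_mm, gm)
                static[net][i] = vals
            if "dynamic" in kinds:
                for sch in schemes:
                    cv = dynamic_cv_map(
                        clean, seed_masks[net], gm, sch,
                        variability_kind=config.variability_kind, seed=spec,
                    )
                    vals = smooth_volume(cv.values, vox, config.smooth_fwhm_mm, gm)
                    dynamic[(net, (sch.length_tr, sch.step_tr))][i] = vals
        if progress is not None:
            progress(i + 1, n)
    return SubjectMaps(static, dynamic, table, masks)


def group_cluster_analysis(
    maps: np.ndarray,
    table: pd.DataFrame,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    network: str | None = None,
) -> tuple[list[ClusterResult], "object"]:
    """ANCOVA + smoothness estimation + GRF cluster correction in one call.

    Returns the surviving clusters (network tag attached) and the raw
    ANCOVA result.
    """
    design = build_design(table)
    res = voxelwise_ancova(maps, design, mask)
    sm = estimate_smoothness(res.std_residuals, mask)
    clusters = grf_cluster_threshold(
        res.f_map, res.df1, res.df2, sm, mask, affine,
        voxel_p=voxel_p, cluster_p=cluster_p,
    )
    for c in clusters:
        c.network = network
    return clusters, res


def write_cluster_report(clusters: list[ClusterResult], path) -> Path:
    """TSV with one row per surviving cluster, mirroring the study's
    cluster-table schema; floats carry 3 decimals."""
    rows = [
        dict(
            brain_network=c.network or "NA",
            anatomical_region=getattr(c, "anatomical_region", "NA") or "NA",
            number_of_voxels=c.n_voxels,
            peak_mni_x=c.peak_mni[0],
            peak_mni_y=c.peak_mni[1],
            peak_mni_z=c.peak_mni[2],
            peak_intensity=c.peak_stat,
        )
        for c in clusters
    ]
    df = pd.DataFrame(rows, columns=CLUSTER_REPORT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def read_cluster_report(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def spatial_similarity(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two maps over the mask voxels."""
    a, b = map_a[mask], map_b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


@dataclass
class RunResult:
    out_dir: Path
    table: pd.DataFrame
    clusters_static: list[ClusterResult]
    clusters_dynamic: list[ClusterResult]
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    scheme_similarity: pd.DataFrame
    provenance: dict
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by ``config``; see module
    docstring for the stage order.  Identical config + seed gives
    byte-identical reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t_start = time.perf_counter()

    def stage(name):
        log.append(f"[{time.perf_counter() - t_start:8.2f}s] {name}")

    stage("generate participants")
    table = generate_participants(config.n_per_group, rng_seed=config.rng_seed)

    stage("simulate + preprocess + connectivity")
    try:
        subj = compute_subject_maps(table, config.scene, config)
    except Exception as exc:  # annotate stage context per the run contract
        raise RuntimeError(f"stage 'connectivity' failed: {exc}") from exc
    table = subj.table
    gm = subj.masks["gm"]
    aff = config.scene.affine

    stage("group statistics")
    clusters_static: list[ClusterResult] = []
    clusters_dynamic: list[ClusterResult] = []
    primary_scheme = config.window_schemes[0]
    for net in config.networks:
        cs, _ = group_cluster_analysis(
            subj.static[net], table, gm, aff,
            config.voxel_p, config.cluster_p, network=net,
        )
        clusters_static.extend(cs)
        cd, _ = group_cluster_analysis(
            subj.dynamic[(net, primary_scheme)], table, gm, aff,
            config.voxel_p, config.cluster_p, network=net,
        )
        clusters_dynamic.extend(cd)

    stage("post hoc + correlations")
    posthoc_rows = []
    cluster_values: dict[str, np.ndarray] = {}
    groups = table["group"].to_numpy()
    for kind, clusters in (("static", clusters_static), ("dynamic", clusters_dynamic)):
        for c in clusters:
            maps = (
                subj.static[c.network]
                if kind == "static"
                else subj.dynamic[(c.network, primary_scheme)]
            )
            vals = extract_cluster_values(maps, c)
            name = f"{kind}_{c.network}_c{c.cluster_id}"
            cluster_values[name] = vals
            for cmp_ in posthoc_pairwise(vals, groups, config.posthoc_alphas):
                posthoc_rows.append(
                    dict(
                        cluster=name, pair="-".join(cmp_.pair),
                        t=cmp_.t_stat, p_raw=cmp_.p_raw,
                        p_bonferroni=cmp_.p_adjusted,
                        significance=cmp_.significance,
                    )
                )
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=["cluster", "pair", "t", "p_raw", "p_bonferroni", "significance"],
    )
    if cluster_values:
        correlations = fc_cognition_correlations(table, cluster_values)
    else:
        correlations = pd.DataFrame(
            columns=["cluster", "score", "r", "p_raw", "p_adjusted"]
        )

    stage("window-scheme validation")
    sim_rows = []
    if len(config.window_schemes) > 1:
        ref = config.window_schemes[0]
        for other in config.window_schemes[1:]:
            for net in config.networks:
                a = subj.dynamic[(net, ref)].mean(axis=0)
                b = subj.dynamic[(net, other)].mean(axis=0)
                sim_rows.append(
                    dict(
                        network=net, scheme_a=f"{ref[0]}TR/{ref[1]}TR",
                        scheme_b=f"{other[0]}TR/{other[1]}TR",
                        spatial_pearson=spatial_similarity(a, b, gm),
                    )
                )
    scheme_similarity = pd.DataFrame(
        sim_rows, columns=["network", "scheme_a", "scheme_b", "spatial_pearson"]
    )

    stage("write reports")
    provenance = dict(
        config_hash=config.config_hash(),
        rng_seed=config.rng_seed,
        seedfc_version=__version__,
        numpy_version=np.__version__,
    )
    write_cluster_report(clusters_static, out / "cluster_report_static.tsv")
    write_cluster_report(clusters_dynamic, out / "cluster_report_dynamic.tsv")
    posthoc.to_csv(out / "posthoc.tsv", sep="\t", index=False, float_format="%.6g")
    correlations.to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    demographics_table(table).to_csv(
        out / "table1.tsv", sep="\t", index=False, float_format="%.3f"
    )
    scheme_similarity.to_csv(
        out / "scheme_similarity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    stage("done")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return RunResult(
        out, table, clusters_static, clusters_dynamic, posthoc,
        correlations, scheme_similarity, provenance, log,
    )
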