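"""File interchange: NIfTI images, motion text files, TSV tables, scene YAML."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import Z_CLIP_EPS, DfcCvMap, FcZMap, WindowScheme
from .image import Bold4D
from .simulate import Region, SimScene


def save_bold(img: Bold4D, path) -> None:
    nii = nib.Nifti1Image(np.asarray(img.data), img.affine)
    nii.header.set_zooms((*img.voxel_sizes, img.tr))
    nii.to_filename(str(path))


def load_bold(path, tr: float | None = None) -> Bold4D:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj)
    if tr is None:
        zooms = nii.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if tr is None:
        raise ValueError(f"{path}: TR not recorded in header; pass tr=")
    return Bold4D(data, nii.affine, tr)


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.Nifti1Image(mask.astype(np.uint8), affine).to_filename(str(path))


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    nii = nib.load(str(path))
    return np.asanyarray(nii.dataobj) > 0, nii.affine


def save_fc_map(fc_map, affine: np.ndarray, path) -> Path:
    """Write an FcZMap / DfcCvMap as NIfTI plus a JSON sidecar recording the
    map's provenance (seed, window scheme, variability kind, clipping
    epsilon, smoothing FWHM)."""
    path = Path(path)
    nib.Nifti1Image(np.asarray(fc_map.values, dtype=np.float64), affine).to_filename(
        str(path)
    )
    meta: dict = {
        "r_clip_eps": Z_CLIP_EPS,
        "smoothed_fwhm_mm": fc_map.smoothed_fwhm_mm,
    }
    if fc_map.seed is not None:
        meta["seed"] = dict(
            name=fc_map.seed.name, network=fc_map.seed.network,
            center_mni=list(fc_map.seed.center_mni),
            diameter_mm=fc_map.seed.diameter_mm,
        )
    if isinstance(fc_map, DfcCvMap):
        meta["map_type"] = "dfc_variability"
        meta["variability_kind"] = fc_map.variability_kind
        meta["window_scheme"] = dict(
            length_tr=fc_map.scheme.length_tr, step_tr=fc_map.scheme.step_tr,
            taper=fc_map.scheme.taper,
        )
    else:
        meta["map_type"] = "static_fc_z"
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def load_fc_map(path):
    """Read a map written by :func:`save_fc_map`; returns the matching map
    type with metadata restored (mask is all-true; it is not serialized)."""
    from .connectivity import SeedSpec

    path = Path(path)
    nii = nib.load(str(path))
    values = np.asanyarray(nii.dataobj)
    meta = json.loads(path.with_suffix(".json").read_text())
    seed = None
    if "seed" in meta:
        sd = meta["seed"]
        seed = SeedSpec(
            sd["name"], sd["network"], tuple(sd["center_mni"]), sd["diameter_mm"]
        )
    mask = np.ones(values.shape, dtype=bool)
    if meta["map_type"] == "dfc_variability":
        ws = meta["window_scheme"]
        return DfcCvMap(
            values, mask, seed=seed,
            scheme=WindowScheme(ws["length_tr"], ws["step_tr"], ws["taper"]),
            variability_kind=meta["variability_kind"],
            smoothed_fwhm_mm=meta["smoothed_fwhm_mm"],
        )
    return FcZMap(values, mask, seed=seed, smoothed_fwhm_mm=meta["smoothed_fwhm_mm"])


def write_motion(motion: np.ndarray, path) -> None:
    """6-column whitespace-delimited rigid-body parameters
    (3 translations mm, 3 rotations radians)."""
    np.savetxt(str(path), np.asarray(motion, dtype=float), fmt="%.10g")


def read_motion(path) -> np.ndarray:
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have 6 columns, found {arr.shape[1]}"
        )
    return arr


def write_participants(table: pd.DataFrame, path) -> None:
    table.to_csv(str(path), sep="\t", index=False, float_format="%.6g")


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def scene_to_yaml(scene: SimScene, path) -> None:
    doc = dict(
        grid_shape=list(scene.grid_shape),
        voxel_size=scene.voxel_size,
        tr=scene.tr,
        n_volumes=scene.n_volumes,
        origin_mni=list(scene.origin_mni),
        regions=[
            dict(
                name=r.name, center_voxel=list(r.center_voxel),
                radius_voxels=r.radius_voxels, network=r.network,
                is_seed=r.is_seed,
            )
            for r in scene.regions
        ],
        static_coupling={g: dict(v) for g, v in scene.static_coupling.items()},
        dynamic_coupling_sd={
            g: dict(v) for g, v in scene.dynamic_coupling_sd.items()
        },
        coupling_timescale=scene.coupling_timescale,
        latent_band=list(scene.latent_band),
        noise_sd=scene.noise_sd,
        drift_amplitude=scene.drift_amplitude,
        motion_step_mm=scene.motion_step_mm,
        motion_step_rad=scene.motion_step_rad,
        motion_coupling=scene.motion_coupling,
        wm_csf_amplitude=scene.wm_csf_amplitude,
        rng_seed=scene.rng_seed,
    )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def scene_from_yaml(path) -> SimScene:
    doc = yaml.safe_load(Path(path).read_text())
    regions = [
        Region(
            name=r["name"], center_voxel=tuple(r["center_voxel"]),
            radius_voxels=float(r["radius_voxels"]), network=r["network"],
            is_seed=bool(r.get("is_seed", False)),
        )
        for r in doc.pop("regions")
    ]
    doc["grid_shape"] = tuple(doc["grid_shape"])
    doc["origin_mni"] = tuple(doc["origin_mni"])
    doc["latent_band"] = tuple(doc["latent_band"])
    return SimScene(regions=regions, **doc)


def write_cohort(bundle, outdir) -> Path:
    """Write a materialized cohort: per-subject BOLD NIfTI + motion text,
    tissue masks, participant TSV and the scene YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_participants(bundle.participants, outdir / "participants.tsv")
    scene_to_yaml(bundle.scene, outdir / "scene.yaml")
    aff = bundle.scene.affine
    for name in ("gm", "wm", "csf"):
        save_mask(bundle.masks[name], aff, outdir / f"mask_{name}.nii")
    for sid, img in bundle.bolds.items():
        save_bold(img, outdir / f"{sid}_bold.nii")
        write_motion(bundle.motions[sid], outdir / f"{sid}_motion.txt")
    return outdir
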