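"""Synthetic resting-state BOLD cohorts with planted network structure.

The generator produces desk-scale three-group cohorts (AD / aMCI / NC) whose
statistical structure matches what the seed-based static/dynamic FC analysis
assumes: each network carries a band-limited latent signal s(t); voxels in a
network region follow

    y(t) = (a_g + b(t)) * s(t) + drift + motion artifact + WM/CSF signal + noise

where ``a_g`` is the group's static coupling strength and ``b(t)`` is a
zero-mean AR(1) process with stationary SD ``tau_g`` — the group's coupling
*variability*.  The two parameters independently control the two readouts of
the analysis: mean seed connectivity (static FC) and windowed-FC variability.
Seed regions carry the latent signal itself with unit coupling.

Everything is a pure, bit-reproducible function of (scene, participant
table, seed).  Off-network voxels contain nuisance and noise only.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import Bold4D

GROUPS = ("AD", "aMCI", "NC")

#: Per-group demographic distributions used by :func:`generate_participants`.
#: Continuous variables are (mean, sd); sex is a male fraction; mean_fd is the
#: nominal head-movement summary (overwritten with the realized value when a
#: motion trace is simulated).
DEFAULT_DEMOGRAPHICS: dict[str, dict] = {
    "AD": dict(
        age=(66.830, 7.849), education=(7.359, 4.359),
        mmse=(18.717, 4.538), moca=(5.492, 0.754),
        male_fraction=20 / 53, mean_fd=(0.12, 0.04),
    ),
    "aMCI": dict(
        age=(66.225, 8.313), education=(7.350, 3.051),
        mmse=(26.275, 0.877), moca=(22.650, 2.327),
        male_fraction=23 / 40, mean_fd=(0.12, 0.04),
    ),
    "NC": dict(
        age=(65.850, 9.178), education=(7.375, 3.378),
        mmse=(28.950, 0.904), moca=(27.350, 1.350),
        male_fraction=19 / 40, mean_fd=(0.12, 0.04),
    ),
}

PARTICIPANT_COLUMNS = [
    "id", "group", "age", "sex", "education", "mmse", "moca", "mean_fd",
]


@dataclass(frozen=True)
class Region:
    """A spherical network region on the voxel grid.

    ``is_seed`` marks the region whose voxels carry the latent network
    signal directly (coupling 1, no temporal modulation); other regions of
    the same network are coupled to it with group-dependent strength.
    """

    name: str
    center_voxel: tuple[int, int, int]
    radius_voxels: float
    network: str
    is_seed: bool = False


@dataclass
class SimScene:
    """Generative description of a synthetic cohort.

    Parameters
    ----------
    regions : list of Region
        Network regions planted on the grid.
    static_coupling : dict
        ``{group: {region_name: a_g}}`` mean coupling for every non-seed
        region (unitless).
    dynamic_coupling_sd : dict
        ``{group: {region_name: tau_g}}`` stationary SD of the slow AR(1)
        coupling process (unitless).
    coupling_timescale : float
        AR(1) correlation time of b(t), seconds.  40 s by default: slow
        enough to be 'dynamic coupling' rather than noise, fast enough to
        vary across 100 s sliding windows.
    spatial_fwhm_vox : float
        Intrinsic spatial smoothness (FWHM, voxel units) of the thermal
        noise.  2 voxels (6 mm at 3 mm resolution) emulates the point-spread
        of EPI acquisition plus interpolation; spatially white noise (0)
        violates the smooth-field assumption of cluster-level random field
        inference.
    latent_band : (float, float)
        Pass band of the latent network signals, Hz.  (0.01, 0.08) keeps
        post-bandpass power non-degenerate.
    noise_sd, drift_amplitude, motion_coupling, wm_csf_amplitude : float
        Nuisance amplitudes relative to the unit-SD latent signal.
    motion_step_mm, motion_step_rad : float
        Per-volume random-walk step SD of the 6 rigid-body parameters.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    tr: float = 2.0
    n_volumes: int = 210
    origin_mni: tuple[float, float, float] = (-36.0, -36.0, -36.0)
    regions: list[Region] = field(default_factory=list)
    static_coupling: dict[str, dict[str, float]] = field(default_factory=dict)
    dynamic_coupling_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    coupling_timescale: float = 40.0
    latent_band: tuple[float, float] = (0.01, 0.08)
    noise_sd: float = 1.0
    spatial_fwhm_vox: float = 2.0
    drift_amplitude: float = 0.5
    motion_step_mm: float = 0.02
    motion_step_rad: float = 2e-4
    motion_coupling: float = 0.2
    wm_csf_amplitude: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.eye(3) * self.voxel_size
        aff[:3, 3] = self.origin_mni
        return aff

    def validate(self) -> None:
        if not float(self.noise_sd) > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        shape = np.asarray(self.grid_shape)
        for reg in self.regions:
            c = np.asarray(reg.center_voxel)
            if np.any(c - reg.radius_voxels < -0.5) or np.any(
                c + reg.radius_voxels > shape - 0.5
            ):
                raise ValueError(f"region {reg.name!r} does not lie inside the grid")
        for group, taus in self.dynamic_coupling_sd.items():
            for name, tau in taus.items():
                if tau < 0:
                    raise ValueError(
                        f"dynamic_coupling_sd[{group}][{name}] must be >= 0"
                    )

    def check_supports_windows(self, window_len_tr: int, n_drop: int = 10) -> None:
        """Fail early if the series is too short for a window scheme."""
        if self.n_volumes <= window_len_tr + n_drop:
            raise ValueError(
                f"n_volumes={self.n_volumes} does not exceed window length "
                f"{window_len_tr} plus {n_drop} discarded volumes"
            )

    def group_params(self, group: str, region: Region) -> tuple[float, float]:
        """(a_g, tau_g) for a non-seed region; raises if unconfigured."""
        try:
            a = self.static_coupling[group][region.name]
            tau = self.dynamic_coupling_sd[group][region.name]
        except KeyError as exc:
            raise ValueError(
                f"no coupling parameters for group {group!r}, "
                f"region {region.name!r}"
            ) from exc
        return float(a), float(tau)


# --------------------------------------------------------------------------
# participants
# --------------------------------------------------------------------------

def generate_participants(
    n_per_group: tuple[int, int, int] = (53, 40, 40),
    demo_params: dict | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw a Table-1-style participant table.

    Continuous variables come from per-group normal distributions;
    MMSE/MoCA are clipped to the 0-30 instrument range; sex is Bernoulli
    with the per-group male fraction.  Deterministic under ``rng_seed``.
    """
    demo_params = demo_params if demo_params is not None else DEFAULT_DEMOGRAPHICS
    if len(n_per_group) != len(GROUPS):
        raise ValueError(f"n_per_group must have {len(GROUPS)} entries")
    for n in n_per_group:
        if int(n) < 2:
            raise ValueError("every group needs at least 2 subjects")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for group, n in zip(GROUPS, n_per_group):
        n = int(n)
        p = demo_params[group]
        age = rng.normal(*p["age"], size=n)
        edu = np.clip(rng.normal(*p["education"], size=n), 0, None)
        mmse = np.clip(rng.normal(*p["mmse"], size=n), 0, 30)
        moca = np.clip(rng.normal(*p["moca"], size=n), 0, 30)
        male = rng.random(n) < p["male_fraction"]
        fd = np.clip(rng.normal(*p["mean_fd"], size=n), 0.005, None)
        for i in range(n):
            rows.append(
                dict(
                    id=f"sub-{group}{i + 1:03d}", group=group,
                    age=age[i], sex="M" if male[i] else "F",
                    education=edu[i], mmse=mmse[i], moca=moca[i],
                    mean_fd=fd[i],
                )
            )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


# --------------------------------------------------------------------------
# tissue geometry
# --------------------------------------------------------------------------

def tissue_masks(scene: SimScene) -> dict[str, np.ndarray]:
    """Gray-matter / white-matter / CSF masks for the scene's grid.

    A brain ellipsoid (semi-axes 0.45 x grid) holds a central white-matter
    ball which itself encloses a CSF ('ventricle') ball; gray matter is the
    remaining shell.  Crude, but it gives the analysis a gray-matter mask
    and the nuisance model WM/CSF compartments with shared signals.
    """
    shape = np.asarray(scene.grid_shape)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    d = (idx - center) / semi
    brain = (d ** 2).sum(axis=-1) <= 1.0
    r = np.sqrt(((idx - center) ** 2).sum(axis=-1))
    wm_r = 0.20 * shape.min()
    csf_r = 0.10 * shape.min()
    csf = r <= csf_r
    wm = (r <= wm_r) & ~csf
    gm = brain & (r > wm_r)
    return {"gm": gm, "wm": wm, "csf": csf, "brain": brain}


def region_mask(region: Region, grid_shape: tuple[int, int, int]) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    d2 = ((idx - np.asarray(region.center_voxel)) ** 2).sum(axis=-1)
    return d2 <= region.radius_voxels ** 2


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------

def band_limited_noise(
    n: int, tr: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise with spectral support restricted to ``band``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("band contains no representable frequency")
    spec[~keep] = 0.0
    sig = np.fft.irfft(spec, n=n)
    sd = sig.std()
    if sd == 0:
        raise ValueError("degenerate band-limited signal")
    return sig / sd


def ar1_process(
    n: int, sd: float, tr: float, timescale: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean stationary AR(1) sample with SD ``sd`` and the given
    correlation time (phi = exp(-TR / timescale))."""
    draws = rng.standard_normal(n)  # drawn even when sd == 0: stable stream
    if sd == 0:
        return np.zeros(n)
    phi = float(np.exp(-tr / timescale))
    x = np.empty(n)
    x[0] = draws[0]
    innov = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov * draws[t]
    return sd * x


def _spatially_smooth_noise(
    noise: np.ndarray, cache: dict, shape: tuple[int, int, int], fwhm_vox: float
) -> np.ndarray:
    """Give brain-voxel noise the intrinsic spatial smoothness of EPI data,
    renormalized so interior voxels keep unit variance."""
    from scipy.ndimage import gaussian_filter, gaussian_filter1d

    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    dense = np.zeros((int(np.prod(shape)), noise.shape[1]), dtype=noise.dtype)
    dense[cache["flat_brain"]] = noise
    dense = dense.reshape(*shape, noise.shape[1])
    dense = gaussian_filter(dense, sigma=(sigma, sigma, sigma, 0.0), mode="constant")
    # exact variance of the truncated discrete kernel, one axis
    impulse = np.zeros(2 * int(4 * sigma + 1) + 1)
    impulse[len(impulse) // 2] = 1.0
    ssq = float((gaussian_filter1d(impulse, sigma, mode="constant") ** 2).sum())
    out = dense.reshape(-1, noise.shape[1])[cache["flat_brain"]]
    out /= ssq ** 1.5
    return out


def simulate_motion(scene: SimScene, rng: np.random.Generator) -> np.ndarray:
    """A (n_volumes, 6) rigid-body random walk: 3 translations (mm) then
    3 rotations (radians)."""
    steps = rng.standard_normal((scene.n_volumes, 6))
    steps[:, :3] *= scene.motion_step_mm
    steps[:, 3:] *= scene.motion_step_rad
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def mean_framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> float:
    """Mean Power framewise displacement: sum of absolute backward
    differences, rotations converted to arc length on a 50 mm sphere."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must have 6 columns")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return float(fd.mean())


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

def _subject_rng(scene: SimScene, subject_id: str) -> np.random.Generator:
    # stable per-subject stream: scene seed + CRC32 of the subject id
    return np.random.default_rng([int(scene.rng_seed), zlib.crc32(subject_id.encode())])


def _scene_cache(scene: SimScene) -> dict:
    """Precomputed geometry shared by every subject of a scene.

    Scenes are treated as immutable after construction; the cache lives on
    the instance.
    """
    cache = scene.__dict__.get("_cache")
    if cache is not None:
        return cache
    shape = tuple(scene.grid_shape)
    masks = tissue_masks(scene)
    brain = masks["brain"] | masks["wm"] | masks["csf"]
    flat_brain = np.flatnonzero(brain.reshape(-1))
    pos = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    pos[flat_brain] = np.arange(flat_brain.size)

    def rows(mask3d: np.ndarray) -> np.ndarray:
        r = pos[np.flatnonzero(mask3d.reshape(-1))]
        if np.any(r < 0):
            raise ValueError("region extends outside the simulated brain volume")
        return r

    cache = dict(
        masks=masks,
        brain=brain,
        flat_brain=flat_brain,
        n_brain=flat_brain.size,
        rows_gm=rows(masks["gm"]),
        rows_wm=rows(masks["wm"]),
        rows_csf=rows(masks["csf"]),
        region_rows={
            reg.name: rows(region_mask(reg, shape)) for reg in scene.regions
        },
    )
    scene.__dict__["_cache"] = cache
    return cache


def simulate_bold(
    record,
    scene: SimScene,
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> tuple[Bold4D, np.ndarray, dict[str, np.ndarray]]:
    """Simulate one subject's BOLD run.

    Parameters
    ----------
    record : mapping
        Needs ``id`` and ``group`` (a participant-table row works).
    rng : Generator, optional
        Supply to control the stream; by default a per-subject stream is
        derived from ``scene.rng_seed`` and the subject id.

    Returns
    -------
    (Bold4D, motion trace (n_volumes, 6), tissue masks dict)
    """
    group = record["group"]
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    # fail before burning RNG draws if any region lacks parameters
    for reg in scene.regions:
        if not reg.is_seed:
            scene.group_params(group, reg)
    if rng is None:
        rng = _subject_rng(scene, str(record["id"]))
    T = scene.n_volumes
    shape = tuple(scene.grid_shape)
    cache = _scene_cache(scene)
    masks = cache["masks"]
    nb = cache["n_brain"]

    motion = simulate_motion(scene, rng)

    networks = sorted({reg.network for reg in scene.regions})
    latents = {
        net: band_limited_noise(T, scene.tr, scene.latent_band, rng)
        for net in networks
    }

    # brain voxels only: voxels outside the brain ellipsoid carry no signal
    # (and never enter the analysis mask or nuisance means)
    data = np.zeros((nb, T), dtype=dtype)
    for reg in sorted(scene.regions, key=lambda r: r.name):
        s = latents[reg.network]
        if reg.is_seed:
            sig = s
            _ = ar1_process(T, 0.0, scene.tr, scene.coupling_timescale, rng)
        else:
            a, tau = scene.group_params(group, reg)
            b = ar1_process(T, tau, scene.tr, scene.coupling_timescale, rng)
            sig = (a + b) * s
        data[cache["region_rows"][reg.name]] += sig.astype(dtype)

    # shared WM/CSF signals: full strength in their compartment, attenuated
    # leakage into gray matter (what nuisance regression is meant to remove)
    g_wm = band_limited_noise(T, scene.tr, scene.latent_band, rng)
    g_csf = band_limited_noise(T, scene.tr, scene.latent_band, rng)
    amp = scene.wm_csf_amplitude
    data[cache["rows_wm"]] += (amp * g_wm).astype(dtype)
    data[cache["rows_csf"]] += (amp * g_csf).astype(dtype)
    data[cache["rows_gm"]] += (0.3 * amp * (g_wm + g_csf)).astype(dtype)

    # per-voxel linear drift over the scan
    ramp = (np.arange(T) / max(T - 1, 1) - 0.5).astype(dtype)
    slopes = (scene.drift_amplitude * rng.standard_normal(nb)).astype(dtype)
    data += slopes[:, None] * ramp[None, :]

    # motion-correlated artifact: random voxel loadings on the standardized
    # rigid-body parameters
    msd = motion.std(axis=0)
    msd[msd == 0] = 1.0
    mstd = ((motion - motion.mean(axis=0)) / msd).T  # (6, T)
    loadings = rng.standard_normal((nb, 6)) * (scene.motion_coupling / np.sqrt(6))
    data += (loadings @ mstd).astype(dtype)

    noise = rng.standard_normal(
        (nb, T), dtype=np.float32 if dtype == np.float32 else np.float64
    )
    if scene.spatial_fwhm_vox > 0:
        noise = _spatially_smooth_noise(noise, cache, shape, scene.spatial_fwhm_vox)
    data += (scene.noise_sd * noise).astype(dtype)

    full = np.zeros((int(np.prod(shape)), T), dtype=dtype)
    full[cache["flat_brain"]] = data
    img = Bold4D(full.reshape(*shape, T), scene.affine, scene.tr)
    return img, motion, masks


@dataclass
class CohortBundle:
    """A fully materialized synthetic cohort (small scenes only: holds every
    subject's 4D image in memory — use :func:`iter_cohort` at scale)."""

    participants: pd.DataFrame
    bolds: dict[str, Bold4D]
    motions: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    scene: SimScene


def iter_cohort(table: pd.DataFrame, scene: SimScene, dtype=np.float64):
    """Yield ``(record, bold, motion)`` per subject, streaming.

    The yielded record's ``mean_fd`` is replaced by the mean framewise
    displacement realized by the simulated motion trace, so the
    head-movement covariate used downstream describes the actual data.
    """
    for _, row in table.iterrows():
        img, motion, _ = simulate_bold(row, scene, dtype=dtype)
        rec = row.copy()
        rec["mean_fd"] = mean_framewise_displacement(motion)
        yield rec, img, motion


def simulate_cohort(table: pd.DataFrame, scene: SimScene, dtype=np.float64) -> CohortBundle:
    """Materialize a full cohort bundle (images, motion, masks, table)."""
    bolds, motions = {}, {}
    table = table.copy().reset_index(drop=True)
    for i, (rec, img, motion) in enumerate(iter_cohort(table, scene, dtype=dtype)):
        bolds[rec["id"]] = img
        motions[rec["id"]] = motion
        table.loc[i, "mean_fd"] = rec["mean_fd"]
    return CohortBundle(table, bolds, motions, tissue_masks(scene), scene)


def assert_null_scene(scene: SimScene) -> None:
    """Raise unless every group's coupling parameters are identical (the
    exchangeability contract of a null cohort)."""
    for params in (scene.static_coupling, scene.dynamic_coupling_sd):
        if not params:
            continue
        values = [params[g] for g in GROUPS if g in params]
        if any(v != values[0] for v in values[1:]):
            raise ValueError(
                "null cohort requires identical coupling parameters in all groups"
            )


def simulate_null_cohort(
    n_per_group: tuple[int, int, int],
    scene: SimScene,
    rng_seed: int = 0,
    dtype=np.float64,
) -> CohortBundle:
    """A cohort that is exchangeable across group labels, for calibrating
    the family-wise error of the corrected pipeline.  Refuses scenes whose
    groups differ in any coupling parameter."""
    assert_null_scene(scene)
    table = generate_participants(n_per_group, rng_seed=rng_seed)
    return simulate_cohort(table, scene, dtype=dtype)


# --------------------------------------------------------------------------
# scene factories
# --------------------------------------------------------------------------

#: Published seed coordinates of the three networks (MNI mm).
SEED_MNI = {
    "DMN": ("PCC", (0.0, -53.0, 26.0)),
    "SN": ("dACC", (10.0, 34.0, 24.0)),
    "CEN": ("dlPFC", (30.0, 12.0, 60.0)),
}

DEFAULT_STATIC_COUPLING = {"AD": 0.40, "aMCI": 0.55, "NC": 0.70}
DEFAULT_DYNAMIC_SD = {"AD": 0.35, "aMCI": 0.15, "NC": 0.25}


def default_scene(
    networks: tuple[str, ...] = ("DMN",),
    grid_shape: tuple[int, int, int] | None = None,
    static_coupling: dict[str, float] | None = None,
    dynamic_coupling_sd: dict[str, float] | None = None,
    region_radius_voxels: float = 2.0,
    rng_seed: int = 0,
    **scene_kwargs,
) -> SimScene:
    """Build a ready-to-run scene for one or more networks.

    Each network gets a seed region plus one coupled target region.  With a
    single network the affine is chosen so the seed voxel maps exactly onto
    the network's published MNI seed coordinate; with several networks a
    fixed whole-grid affine is used and seeds land on the nearest voxel.
    ``static_coupling`` / ``dynamic_coupling_sd`` are per-group values
    applied to every target region (defaults plant group-distinct effects).
    """
    static_coupling = dict(static_coupling or DEFAULT_STATIC_COUPLING)
    dynamic_coupling_sd = dict(dynamic_coupling_sd or DEFAULT_DYNAMIC_SD)
    for net in networks:
        if net not in SEED_MNI:
            raise ValueError(f"unknown network {net!r}")

    regions: list[Region] = []
    if len(networks) == 1:
        net = networks[0]
        grid_shape = grid_shape or (24, 24, 24)
        shape = np.asarray(grid_shape)
        center = (shape - 1) // 2
        # center the regions in the gray-matter shell (between the WM ball
        # at 0.20*min and the brain ellipsoid at 0.45*grid) and shrink the
        # radius if a small grid cannot host the requested one
        off = int(round(0.325 * shape.min()))
        radius = float(min(region_radius_voxels, 0.45 * shape.min() - off - 0.8))
        if radius <= 0:
            raise ValueError(f"grid {tuple(grid_shape)} is too small for a region")
        seed_vox = tuple(int(v) for v in center + np.array([0, 0, off]))
        target_vox = tuple(int(v) for v in center - np.array([0, 0, off]))
        seed_name, mni = SEED_MNI[net]
        origin = tuple(np.asarray(mni) - 3.0 * np.asarray(seed_vox))
        regions.append(Region(seed_name, seed_vox, radius, net, True))
        regions.append(Region(f"{net}_target", target_vox, radius, net))
    else:
        # fixed whole-grid affine chosen so all three published seed
        # coordinates (and their reflected targets) sit inside the brain
        grid_shape = grid_shape or (36, 42, 36)
        shape = np.asarray(grid_shape)
        origin = (-50.0, -74.0, -16.0)
        center = (shape - 1) / 2.0
        for net in networks:
            seed_name, mni = SEED_MNI[net]
            seed_vox = tuple(
                int(v) for v in np.round((np.asarray(mni) - origin) / 3.0)
            )
            target_vox = tuple(int(v) for v in np.round(2 * center - seed_vox))
            regions.append(Region(seed_name, seed_vox, region_radius_voxels, net, True))
            regions.append(Region(f"{net}_target", target_vox, region_radius_voxels, net))

    target_names = [r.name for r in regions if not r.is_seed]
    return SimScene(
        grid_shape=tuple(int(n) for n in grid_shape),
        origin_mni=tuple(float(v) for v in origin),
        regions=regions,
        static_coupling={
            g: {n: static_coupling[g] for n in target_names} for g in GROUPS
        },
        dynamic_coupling_sd={
            g: {n: dynamic_coupling_sd[g] for n in target_names} for g in GROUPS
        },
        rng_seed=rng_seed,
        **scene_kwargs,
    )


def null_scene(
    networks: tuple[str, ...] = ("DMN",),
    static_coupling: float = 0.55,
    dynamic_coupling_sd: float = 0.20,
    **kwargs,
) -> SimScene:
    """A scene whose groups share identical coupling (for FWER calibration)."""
    return default_scene(
        networks,
        static_coupling={g: static_coupling for g in GROUPS},
        dynamic_coupling_sd={g: dynamic_coupling_sd for g in GROUPS},
        **kwargs,
    )
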