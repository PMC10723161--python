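"""Seed-based static and dynamic functional connectivity maps.

Static FC: Pearson correlation between the mean series of a small spherical
seed and every voxel in the analysis mask, Fisher r-to-z transformed.
Dynamic FC: the same correlation inside rectangular sliding windows
(default 50 TR length, 2 TR step), Fisher-z per window, summarized per
voxel by the coefficient of variation (SD across windows divided by the
absolute mean; an SD-only variant is available because the CV denominator
is unstable where the mean windowed z is near zero).

Default seeds are the published triple-network coordinates: PCC for the
default-mode network, dACC for the salience network, dlPFC for the central
executive network, each a 6 mm *diameter* sphere.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import Bold4D, voxel_center_grid_mm

#: r-clipping so Fisher z stays finite: |r| <= 1 - Z_CLIP_EPS.
Z_CLIP_EPS = 1e-7
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SeedSpec:
    """A named spherical seed: network, MNI center (mm), diameter (mm)."""

    name: str
    network: str
    center_mni: tuple[float, float, float]
    diameter_mm: float = 6.0

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")


DEFAULT_SEEDS = (
    SeedSpec("PCC", "DMN", (0.0, -53.0, 26.0)),
    SeedSpec("dACC", "SN", (10.0, 34.0, 24.0)),
    SeedSpec("dlPFC", "CEN", (30.0, 12.0, 60.0)),
)


@dataclass(frozen=True)
class WindowScheme:
    """Rectangular sliding-window bookkeeping (lengths in TR units)."""

    length_tr: int = 50
    step_tr: int = 2
    taper: str = "rectangular"

    def __post_init__(self) -> None:
        if self.length_tr <= 1:
            raise ValueError("length_tr must exceed 1")
        if self.step_tr < 1:
            raise ValueError("step_tr must be >= 1")
        if self.taper != "rectangular":
            raise ValueError(f"unsupported taper {self.taper!r}")


@dataclass
class FcZMap:
    """Per-subject static seed-FC map of Fisher z values."""

    values: np.ndarray
    mask: np.ndarray
    seed: SeedSpec | None = None
    smoothed_fwhm_mm: float = 0.0
    zero_variance: np.ndarray | None = None


@dataclass
class DfcCvMap:
    """Per-subject dynamic-FC variability map across sliding windows."""

    values: np.ndarray
    mask: np.ndarray
    seed: SeedSpec | None = None
    scheme: WindowScheme = field(default_factory=WindowScheme)
    variability_kind: str = "cv"
    smoothed_fwhm_mm: float = 0.0
    sd_fallback: np.ndarray | None = None


def make_sphere_seed(
    spec: SeedSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within diameter/2 mm
    (closed Euclidean ball) of the seed's MNI center."""
    centers = voxel_center_grid_mm(affine, shape)
    lo, hi = centers.reshape(-1, 3).min(axis=0), centers.reshape(-1, 3).max(axis=0)
    c = np.asarray(spec.center_mni, dtype=float)
    if np.any(c < lo - 1e-9) or np.any(c > hi + 1e-9):
        raise ValueError(
            f"seed {spec.name!r} center {tuple(c)} lies outside the grid"
        )
    d2 = ((centers - c) ** 2).sum(axis=-1)
    mask = d2 <= (spec.diameter_mm / 2.0) ** 2 + 1e-9
    if not mask.any():
        raise ValueError(f"seed {spec.name!r} produced an empty voxel mask")
    return mask


def seed_timeseries(img: Bold4D, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean series over the seed voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    ts = img.data[seed_mask].mean(axis=0).astype(np.float64)
    if np.ptp(ts) == 0:
        raise ValueError("seed time series is constant (uninterpretable seed)")
    return ts


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping to +/-(1 - 1e-7) so the transform stays finite."""
    return np.arctanh(np.clip(r, -1 + Z_CLIP_EPS, 1 - Z_CLIP_EPS))


def _masked_series(img: Bold4D, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if mask is None:
        mask = np.ones(img.shape3d, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape3d:
        raise ValueError("analysis mask shape does not match image grid")
    return img.data[mask].astype(np.float64), mask


def static_fc_map(
    img: Bold4D, seed_mask: np.ndarray, mask: np.ndarray | None = None,
    seed: SeedSpec | None = None,
) -> FcZMap:
    """Whole-scan seed-to-voxel Pearson correlation, Fisher transformed.

    Voxels with zero temporal variance get z = 0 and are flagged in
    ``zero_variance``.
    """
    s = seed_timeseries(img, seed_mask)
    Y, mask = _masked_series(img, mask)
    s = s - s.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom_s = np.sqrt((s ** 2).sum())
    denom_y = np.sqrt((Yc ** 2).sum(axis=1))
    flat_zero = denom_y == 0
    denom_y[flat_zero] = 1.0
    r = (Yc @ s) / (denom_y * denom_s)
    r[flat_zero] = 0.0
    z = fisher_z(r)
    values = np.zeros(img.shape3d)
    values[mask] = z
    zv = np.zeros(img.shape3d, dtype=bool)
    zv[mask] = flat_zero
    return FcZMap(values, mask, seed=seed, zero_variance=zv)


def sliding_window_indices(n_volumes: int, scheme: WindowScheme) -> list[tuple[int, int]]:
    """Half-open [start, stop) windows; trailing partial windows discarded.

    Count = floor((n - length) / step) + 1.
    """
    L, s = scheme.length_tr, scheme.step_tr
    if L > n_volumes:
        raise ValueError(
            f"window length {L} exceeds series length {n_volumes}"
        )
    n_win = (n_volumes - L) // s + 1
    return [(k * s, k * s + L) for k in range(n_win)]


def windowed_seed_correlations(
    img: Bold4D, seed_mask: np.ndarray, mask: np.ndarray | None, scheme: WindowScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z seed-to-voxel correlations per sliding window.

    Returns ``(z, mask)`` with ``z`` of shape (n_windows, n_mask_voxels).
    Rectangular windows allow an O(V x T) cumulative-sum evaluation of all
    windowed sums; a windowed series with zero variance yields z = 0.
    """
    s = seed_timeseries(img, seed_mask)
    Y, mask = _masked_series(img, mask)
    windows = sliding_window_indices(img.n_volumes, scheme)
    if len(windows) < 2:
        raise ValueError("need at least 2 sliding windows")
    L = scheme.length_tr
    starts = np.array([a for a, _ in windows])
    stops = np.array([b for _, b in windows])

    def wsum(series_cum: np.ndarray) -> np.ndarray:
        # series_cum: cumulative sums with leading zero, shape (..., T+1)
        return series_cum[..., stops] - series_cum[..., starts]

    pad = lambda x: np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    cs, cs2 = pad(s), pad(s ** 2)
    cy, cy2 = pad(Y), pad(Y ** 2)
    cxy = pad(Y * s[None, :])

    Sx, Sxx = wsum(cs), wsum(cs2)          # (W,)
    Sy, Syy = wsum(cy), wsum(cy2)          # (V, W)
    Sxy = wsum(cxy)                        # (V, W)
    var_x = L * Sxx - Sx ** 2
    var_y = L * Syy - Sy ** 2
    cov = L * Sxy - Sy * Sx[None, :]
    bad = (var_y <= 0) | (var_x[None, :] <= 0)
    var_y = np.where(var_y <= 0, 1.0, var_y)
    vx = np.where(var_x <= 0, 1.0, var_x)
    r = cov / np.sqrt(var_y * vx[None, :])
    r[bad] = 0.0
    np.clip(r, -1 + Z_CLIP_EPS, 1 - Z_CLIP_EPS, out=r)
    return np.arctanh(r).T, mask  # (W, V)


def dynamic_cv_map(
    img: Bold4D,
    seed_mask: np.ndarray,
    mask: np.ndarray | None = None,
    scheme: WindowScheme = WindowScheme(),
    variability_kind: str = "cv",
    mean_eps: float = 0.05,
    seed: SeedSpec | None = None,
) -> DfcCvMap:
    """Variability of windowed seed FC per voxel.

    ``variability_kind='cv'``: sample SD of the windowed z values divided
    by |mean| where |mean| >= ``mean_eps``; voxels below that get the raw
    SD and are flagged in ``sd_fallback`` (the mean-normalization is
    meaningless around zero).  ``'sd'``: plain SD everywhere.
    """
    if variability_kind not in ("cv", "sd"):
        raise ValueError("variability_kind must be 'cv' or 'sd'")
    z, mask = windowed_seed_correlations(img, seed_mask, mask, scheme)
    sd = z.std(axis=0, ddof=1)
    mean = z.mean(axis=0)
    fallback = np.zeros_like(sd, dtype=bool)
    if variability_kind == "cv":
        small = np.abs(mean) < mean_eps
        vals = np.where(small, sd, sd / np.where(small, 1.0, np.abs(mean)))
        fallback = small
    else:
        vals = sd
    values = np.zeros(img.shape3d)
    values[mask] = vals
    fb = np.zeros(img.shape3d, dtype=bool)
    fb[mask] = fallback
    return DfcCvMap(
        values, mask, seed=seed, scheme=scheme,
        variability_kind=variability_kind, sd_fallback=fb,
    )


def smooth_volume(
    values: np.ndarray,
    voxel_sizes_mm: np.ndarray,
    fwhm_mm: float,
    mask: np.ndarray | None = None,
    preserve_mean: bool = True,
) -> np.ndarray:
    """Mask-aware 3D Gaussian smoothing.

    Kernel weights are renormalized at the mask boundary (smoothing never
    mixes values across the mask edge), and the mask mean is restored
    afterwards so edge renormalization cannot bias group-level offsets.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return values.copy()
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / np.asarray(voxel_sizes_mm, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    m = mask.astype(float)
    num = gaussian_filter(values * m, sigma=sigma_vox, mode="constant")
    den = gaussian_filter(m, sigma=sigma_vox, mode="constant")
    out = np.zeros_like(values, dtype=float)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    if preserve_mean and inside.any():
        out[inside] += values[mask].mean() - out[inside].mean()
    return out


def smooth_gaussian(fc_map, fwhm_mm: float = 6.0, voxel_sizes_mm=None):
    """Smooth an :class:`FcZMap` or :class:`DfcCvMap`, returning a new map
    of the same type with ``smoothed_fwhm_mm`` recorded (mask-aware; see
    :func:`smooth_volume`).  ``voxel_sizes_mm`` defaults to 3 mm isotropic."""
    import dataclasses

    if voxel_sizes_mm is None:
        voxel_sizes_mm = np.full(3, 3.0)
    sm = smooth_volume(fc_map.values, voxel_sizes_mm, fwhm_mm, fc_map.mask)
    return dataclasses.replace(fc_map, values=sm, smoothed_fwhm_mm=float(fwhm_mm))
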