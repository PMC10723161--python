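"""Temporal preprocessing of already-aligned BOLD series.

Implements the post-alignment stages of a standard resting-state pipeline:
discard initial volumes, remove a linear trend together with nuisance
signals (Friston-24 motion expansion, white-matter and CSF mean series) in
a single joint least-squares regression, then band-pass filter 0.01-0.1 Hz.
The stage order is fixed: drop -> regression -> bandpass
(:func:`preprocess_bold` is the orchestrator).

Spatial steps (realignment, normalization, slice timing) are out of scope:
inputs are assumed to live on a common grid already.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .image import Bold4D

MOTION_LABELS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class NuisanceMatrix:
    """A volumes x K design of nuisance regressors with column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2D (volumes x K)")
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("nuisance matrix contains non-finite entries")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]


def drop_initial_volumes(img: Bold4D, n_drop: int = 10) -> Bold4D:
    """Remove the first ``n_drop`` volumes (magnetization-equilibration
    scrub).  The caller must truncate motion traces consistently."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= img.n_volumes:
        raise ValueError(
            f"cannot drop {n_drop} of {img.n_volumes} volumes (empty result)"
        )
    if n_drop == 0:
        return img
    return img.with_data(img.data[..., n_drop:])


def build_friston24(motion: np.ndarray) -> NuisanceMatrix:
    """Friston 24-parameter motion expansion.

    Columns: the 6 rigid-body parameters R_t, their one-volume lags
    R_{t-1} (first row zero-filled), then the squares of both.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion trace must have 6 columns, got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 rows")
    lag = np.zeros_like(motion)
    lag[1:] = motion[:-1]
    block = np.hstack([motion, lag, motion ** 2, lag ** 2])
    labels = (
        MOTION_LABELS
        + [f"{m}_lag" for m in MOTION_LABELS]
        + [f"{m}_sq" for m in MOTION_LABELS]
        + [f"{m}_lag_sq" for m in MOTION_LABELS]
    )
    return NuisanceMatrix(block, labels)


def mask_mean_series(img: Bold4D, mask: np.ndarray) -> np.ndarray:
    """Mean time series over a boolean voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape3d:
        raise ValueError("mask shape does not match image grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return img.data[mask].mean(axis=0).astype(float)


def build_nuisance(
    img: Bold4D,
    motion: np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> NuisanceMatrix:
    """Assemble the full confound design: intercept, linear trend,
    Friston-24 motion block, WM mean and CSF mean series."""
    n = img.n_volumes
    if motion.shape[0] != n:
        raise ValueError(
            f"motion trace has {motion.shape[0]} rows for {n} volumes "
            "(truncate it together with dropped volumes)"
        )
    fr = build_friston24(motion)
    cols = [np.ones(n), np.linspace(-0.5, 0.5, n)]
    labels = ["intercept", "linear_trend"]
    cols.append(fr.regressors)
    labels += fr.labels
    if wm_mask is not None:
        cols.append(mask_mean_series(img, wm_mask)[:, None])
        labels.append("wm_mean")
    if csf_mask is not None:
        cols.append(mask_mean_series(img, csf_mask)[:, None])
        labels.append("csf_mean")
    mat = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    return NuisanceMatrix(mat, labels)


def _prune_design(nuisance: NuisanceMatrix) -> tuple[np.ndarray, list[str]]:
    """Drop constant and duplicate columns (keeping the intercept), then
    verify the remaining design is numerically full rank."""
    X = nuisance.regressors
    labels = list(nuisance.labels)
    keep, seen = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        if labels[j] != "intercept" and np.ptp(col) == 0:
            continue  # constant duplicate of the intercept
        if any(np.array_equal(col, X[:, k]) for k in seen):
            continue
        seen.append(j)
        keep.append(j)
    Xk = X[:, keep]
    kept_labels = [labels[j] for j in keep]
    # scale for a meaningful rank test
    scale = np.linalg.norm(Xk, axis=0)
    scale[scale == 0] = 1.0
    rank = np.linalg.matrix_rank(Xk / scale, tol=1e-8)
    if rank < Xk.shape[1]:
        # name the offending columns via tiny R diagonal in a pivoted QR
        _, r = np.linalg.qr(Xk / scale)
        diag = np.abs(np.diag(r))
        bad = [kept_labels[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"nuisance design is rank deficient; collinear columns: {bad}"
        )
    return Xk, kept_labels


def regress_confounds(
    img: Bold4D, nuisance: NuisanceMatrix, mask: np.ndarray | None = None
) -> Bold4D:
    """Replace every voxel series by its least-squares residual against the
    confound design.  Residuals are orthogonal to the design columns (to
    float32 accuracy when the image is stored in float32).

    ``mask`` restricts the computation: voxels outside it are zeroed.
    """
    if nuisance.n_volumes != img.n_volumes:
        raise ValueError(
            f"nuisance rows ({nuisance.n_volumes}) != image volumes "
            f"({img.n_volumes})"
        )
    X, _ = _prune_design(nuisance)
    Q, _ = np.linalg.qr(X)
    if mask is None:
        Y = img.data.reshape(-1, img.n_volumes)
    else:
        mask = np.asarray(mask, dtype=bool)
        Y = img.data[mask]
    work = np.float32 if img.data.dtype == np.float32 else np.float64
    Yw = Y.T.astype(work, copy=True)  # (T, V)
    Qw = Q.astype(work)
    resid = Yw - Qw @ (Qw.T @ Yw)
    if mask is None:
        out = resid.T.reshape(img.data.shape).astype(img.data.dtype, copy=False)
    else:
        out = np.zeros_like(img.data)
        out[mask] = resid.T
    return img.with_data(out)


def bandpass_filter(
    img: Bold4D,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    transition_hw_hz: float = 0.005,
    mask: np.ndarray | None = None,
) -> Bold4D:
    """Temporal band-pass via a frequency-domain filter with raised-cosine
    transition bands.

    The gain is 0 below ``low_hz - hw``, ramps to 1 across
    ``[low - hw, low + hw]`` (so the printed cutoffs sit at -6 dB), stays 1
    through the pass band, and ramps back to 0 across ``[high - hw,
    high + hw]``.  With ``low_hz > 0`` the DC component is removed.
    """
    nyquist = 1.0 / (2.0 * img.tr)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    hw = min(transition_hw_hz, (high_hz - low_hz) / 2.0)
    n = img.n_volumes
    freqs = np.fft.rfftfreq(n, d=img.tr)
    gain = np.ones_like(freqs)
    if low_hz > 0:
        lo0, lo1 = low_hz - hw, low_hz + hw
        below = freqs <= lo0
        ramp = (freqs > lo0) & (freqs < lo1)
        gain[below] = 0.0
        gain[ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp] - lo0) / (lo1 - lo0)))
    hi0, hi1 = high_hz - hw, high_hz + hw
    above = freqs >= hi1
    ramp = (freqs > hi0) & (freqs < hi1)
    gain[above] = 0.0
    gain[ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp] - hi0) / (hi1 - hi0)))

    if mask is None:
        Y = img.data.reshape(-1, n)
    else:
        mask = np.asarray(mask, dtype=bool)
        Y = img.data[mask]
    spec = scipy.fft.rfft(Y, axis=1)  # preserves float32 as complex64
    spec *= gain[None, :].astype(spec.real.dtype)
    filtered = scipy.fft.irfft(spec, n=n, axis=1).astype(img.data.dtype, copy=False)
    if mask is None:
        out = filtered.reshape(img.data.shape)
    else:
        out = np.zeros_like(img.data)
        out[mask] = filtered
    return img.with_data(out)


def preprocess_bold(
    img: Bold4D,
    motion: np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    n_drop: int = 10,
    band_hz: tuple[float, float] = (0.01, 0.1),
    mask: np.ndarray | None = None,
) -> tuple[Bold4D, np.ndarray]:
    """Full temporal preprocessing in the fixed order
    drop -> joint detrend/nuisance regression -> bandpass.

    ``mask`` (e.g. a brain mask) restricts the heavy per-voxel work.
    Returns the cleaned image and the consistently truncated motion trace.
    """
    if motion.shape[0] != img.n_volumes:
        raise ValueError("motion trace length must match the raw image")
    img = drop_initial_volumes(img, n_drop)
    motion = np.asarray(motion, dtype=float)[n_drop:]
    nuis = build_nuisance(img, motion, wm_mask, csf_mask)
    img = regress_confounds(img, nuis, mask=mask)
    img = bandpass_filter(img, *band_hz, mask=mask)
    return img, motion
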