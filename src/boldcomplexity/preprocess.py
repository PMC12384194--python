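"""Light temporal preprocessing of 4-D BOLD volumes.

The chain mirrors common resting-state practice for complexity analysis:
discard equilibration volumes, regress out the six rigid-body motion
parameters, band-pass to the resting-state band (0.008-0.1 Hz), and mask
out-of-brain voxels by thresholding the temporal-mean image at a fraction
of its maximum.  Regression precedes filtering so the filter is not fed
motion-locked variance, and masking uses the *unfiltered* intensities
(band-passed data are zero-mean, so an intensity threshold afterwards
would be meaningless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Volume4D",
    "BrainMask",
    "discard_initial_volumes",
    "regress_nuisance",
    "bandpass",
    "compute_mask",
    "load_motion_params",
]


@dataclass(frozen=True)
class Volume4D:
    """A 4-D BOLD volume: ``data[x, y, z, t]`` plus TR and affine."""

    data: np.ndarray
    tr_seconds: float = 2.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[3] < 1:
            raise ValueError(f"data must be 4-D with t >= 1, got shape {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("volume contains non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class BrainMask:
    """Boolean in-brain mask congruent with one spatial volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not m.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discard_initial_volumes(vol: Volume4D, n_discard: int) -> Volume4D:
    """Drop the first ``n_discard`` volumes (scanner equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= vol.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes"
        )
    return Volume4D(vol.data[..., n_discard:], vol.tr_seconds, vol.affine)


def load_motion_params(path) -> np.ndarray:
    """Read a whitespace-delimited 6-column motion file (one row/volume)."""
    mp = np.loadtxt(path, ndmin=2)
    if mp.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 motion columns, found {mp.shape[1]}"
        )
    return mp


def regress_nuisance(vol: Volume4D, motion: np.ndarray) -> Volume4D:
    """Remove the six motion parameters from every voxel series by OLS.

    The design is [intercept, 6 motion columns]; residuals are returned
    with each voxel's temporal mean added back, so downstream intensity
    masking still sees brain-like values.  Collinear design columns are
    dropped with a warning.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be t x 6, got shape {motion.shape}")
    t = vol.n_volumes
    if motion.shape[0] != t:
        raise ValueError(
            f"motion has {motion.shape[0]} rows but volume has {t} timepoints"
        )
    design = np.column_stack([np.ones(t), motion])
    # drop columns that do not increase rank (constant or collinear regressors)
    keep = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"nuisance design rank-deficient; dropped {design.shape[1] - len(keep)} "
            "collinear column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    x = design[:, keep]
    y = vol.data.reshape(-1, t).T  # t x nvox
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    cleaned = (resid + y.mean(axis=0, keepdims=True)).T.reshape(vol.data.shape)
    return Volume4D(cleaned, vol.tr_seconds, vol.affine)


def bandpass(vol: Volume4D, low_hz: float = 0.008, high_hz: float = 0.1) -> Volume4D:
    """Zero-phase Butterworth band-pass of every voxel series.

    Second-order Butterworth applied forward-backward (effective 4th-order
    magnitude, zero phase).  The band must sit strictly inside
    (0, Nyquist) where Nyquist = 1/(2*TR).
    """
    nyq = 1.0 / (2.0 * vol.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for Nyquist {nyq} Hz"
        )
    sos = sps.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / vol.tr_seconds, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, vol.data, axis=3)
    return Volume4D(filtered, vol.tr_seconds, vol.affine)


def compute_mask(vol: Volume4D, fraction: float = 0.10) -> BrainMask:
    """In-brain mask: temporal-mean intensity above ``fraction`` of its max."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    mean_img = vol.data.mean(axis=3)
    peak = mean_img.max()
    if peak <= 0:
        raise ValueError("all-zero volume: cannot form an intensity mask")
    return BrainMask(mean_img > fraction * peak)
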