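"""Voxel-wise complexity maps and whole-brain summaries.

Applies a scalar complexity estimator (Hurst, fApEn or fSampEn) to every
in-mask voxel of a preprocessed 4-D volume, producing a 3-D metric map
plus bookkeeping (degenerate-voxel mask, parameter snapshot).  Maps are
stored with 0 outside the mask; validity is always carried by the mask,
never inferred from the sentinel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Union

import nibabel as nib
import numpy as np

from .entropy import fuzzy_apen, fuzzy_sampen
from .hurst import hurst_dispersional
from .preprocess import BrainMask, Volume4D
from .series import EntropyParams, HurstParams, UniformTimeSeries

__all__ = [
    "ComplexityMap",
    "WholeBrainSummary",
    "voxelwise_metric",
    "whole_brain_mean",
    "load_volume",
    "save_map",
    "METRICS",
]

METRICS = ("hurst", "fapen", "fsampen")

_METRIC_FUNCS = {
    "hurst": hurst_dispersional,
    "fapen": fuzzy_apen,
    "fsampen": fuzzy_sampen,
}


@dataclass(frozen=True)
class ComplexityMap:
    """Per-voxel metric values with their defining mask and parameters."""

    data: np.ndarray
    mask: BrainMask
    metric: str
    params: Union[EntropyParams, HurstParams]
    degenerate: np.ndarray  # boolean, True where the fallback value was used
    affine: np.ndarray

    @property
    def n_degenerate(self) -> int:
        return int(self.degenerate.sum())


@dataclass(frozen=True)
class WholeBrainSummary:
    """Mean, SD and count of a map over in-mask, non-degenerate voxels."""

    mean: float
    sd: float
    n_voxels: int
    n_degenerate: int
    metric: str


def voxelwise_metric(
    vol: Volume4D,
    mask: BrainMask,
    metric: str,
    params: Union[EntropyParams, HurstParams, None] = None,
) -> ComplexityMap:
    """Compute one complexity metric for every in-mask voxel series.

    ``metric`` is one of 'hurst', 'fapen', 'fsampen'.  Out-of-mask voxels
    are set to the sentinel 0; voxels whose series forced the degenerate
    fallback are flagged and excluded from whole-brain summaries.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if mask.mask.shape != vol.spatial_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match volume "
            f"{vol.spatial_shape}"
        )
    if params is None:
        params = HurstParams() if metric == "hurst" else EntropyParams()
    func = _METRIC_FUNCS[metric]
    out = np.zeros(vol.spatial_shape)
    degen = np.zeros(vol.spatial_shape, dtype=bool)
    coords = np.argwhere(mask.mask)
    for x, y, z in coords:
        ts = UniformTimeSeries(vol.data[x, y, z, :], dt=vol.tr_seconds)
        mv = func(ts, params)
        out[x, y, z] = 0.0 if np.isnan(mv.value) else mv.value
        degen[x, y, z] = mv.degenerate
    return ComplexityMap(out, mask, metric, params, degen, np.asarray(vol.affine))


def whole_brain_mean(cmap: ComplexityMap) -> WholeBrainSummary:
    """Arithmetic mean of map values over in-mask, non-degenerate voxels."""
    valid = cmap.mask.mask & ~cmap.degenerate
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid (in-mask, non-degenerate) voxels to average")
    vals = cmap.data[valid]
    return WholeBrainSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if n > 1 else 0.0,
        n_voxels=n,
        n_degenerate=cmap.n_degenerate,
        metric=cmap.metric,
    )


def load_volume(path) -> Volume4D:
    """Read a 4-D NIfTI-1 file; TR is taken from the header time zoom."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data, tr_seconds=tr, affine=img.affine)


def save_volume(vol: Volume4D, path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], vol.tr_seconds))
    nib.save(img, str(path))


def save_map(cmap: ComplexityMap, path) -> None:
    """Write a 3-D metric map as NIfTI-1, carrying the source affine."""
    nib.save(nib.Nifti1Image(cmap.data, cmap.affine), str(path))


def map_report(cmap: ComplexityMap) -> dict:
    """JSON-ready run report: counts and the parameter snapshot."""
    return {
        "metric": cmap.metric,
        "n_mask_voxels": cmap.mask.n_voxels,
        "n_degenerate": cmap.n_degenerate,
        "params": dataclasses.asdict(cmap.params),
    }
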