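"""Cubic searchlight engine: recompute a multivariate statistic in a sliding
cube neighborhood (default edge 7 voxels -> 343 voxels) across a volume."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class SearchlightSpec:
    edge: int = 7
    min_voxel_frac: float = 0.5  # skip cubes with fewer in-mask voxels than this

    def __post_init__(self) -> None:
        if self.edge < 1 or self.edge % 2 == 0:
            raise ValueError("edge must be a positive odd number of voxels")

    @property
    def cube_voxels(self) -> int:
        return self.edge**3

    @property
    def min_voxels(self) -> int:
        return int(np.ceil(self.min_voxel_frac * self.cube_voxels))


def cube_indices(
    center: tuple[int, int, int], shape: tuple[int, int, int], edge: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel index grids of the cube around ``center``, clipped at the bounds."""
    half = edge // 2
    ranges = [
        np.arange(max(0, c - half), min(n, c + half + 1))
        for c, n in zip(center, shape)
    ]
    return np.meshgrid(*ranges, indexing="ij")


def run_searchlight(
    volume_patterns: np.ndarray,
    mask: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    spec: SearchlightSpec | None = None,
) -> np.ndarray:
    """Per-center-voxel statistic map.

    ``volume_patterns`` is (n_trials, nx, ny, nz); ``statistic`` maps a
    (n_trials, n_cube_voxels) matrix to a scalar.  Cubes are clipped at the
    volume boundary and intersected with the mask; centers whose cube holds
    fewer than ``min_voxel_frac * edge^3`` in-mask voxels yield NaN, as do
    out-of-mask centers.
    """
    spec = spec or SearchlightSpec()
    vols = np.asarray(volume_patterns, float)
    if vols.ndim != 4:
        raise ValueError("volume_patterns must be (n_trials, nx, ny, nz)")
    mask = np.asarray(mask, bool)
    if mask.shape != vols.shape[1:]:
        raise ValueError("mask shape must match the volume shape")

    out = np.full(mask.shape, np.nan)
    flat = vols.reshape(vols.shape[0], -1)
    lin = np.arange(mask.size).reshape(mask.shape)
    for center in zip(*np.nonzero(mask)):
        gx, gy, gz = cube_indices(center, mask.shape, spec.edge)
        in_mask = mask[gx, gy, gz]
        if in_mask.sum() < spec.min_voxels:
            continue
        idx = lin[gx, gy, gz][in_mask]
        out[center] = statistic(flat[:, idx])
    return out
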