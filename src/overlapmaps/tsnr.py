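"""Temporal signal-to-noise ratio and percentile-thresholded voxel masks.

tSNR of a voxel is the mean of its time series divided by its (sample,
n-1) standard deviation.  Within an ROI the voxels are filtered at eight
percentile levels (10th..80th): at level p, voxels with tSNR strictly below
the p-th percentile (linear interpolation) of the ROI's tSNR distribution
are removed; ties with the threshold are kept.  The kept sets are nested
across levels.  Pattern-similarity statistics are computed per level and
averaged across the eight levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

PERCENTILE_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80)


@dataclass(frozen=True)
class TSNRMask:
    roi_name: str
    percentile_level: int
    kept_voxels: np.ndarray  # sorted indices into the ROI's voxel axis

    @property
    def n_kept(self) -> int:
        return len(self.kept_voxels)


def compute_tsnr(timeseries: np.ndarray) -> np.ndarray:
    """Per-voxel mean / sample SD; zero-variance voxels become NaN (warned)."""
    Y = np.asarray(timeseries, float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("timeseries must be (n_timepoints >= 2, n_voxels)")
    sd = Y.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} zero-variance voxel(s) (tSNR undefined)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = Y.mean(axis=0) / np.where(bad, np.nan, sd)
    return t


def threshold_by_percentile(
    tsnr_values: np.ndarray, level: int, roi_name: str = "roi"
) -> TSNRMask:
    """Keep voxels with tSNR >= the level-th percentile (strict-below removal)."""
    if level not in PERCENTILE_LEVELS:
        raise ValueError(f"level must be one of {PERCENTILE_LEVELS}")
    t = np.asarray(tsnr_values, float)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("empty ROI: no finite tSNR values")
    thresh = np.percentile(t[finite], level)
    kept = np.flatnonzero(finite & (t >= thresh))
    return TSNRMask(roi_name, level, kept)


def masks_all_levels(tsnr_values: np.ndarray, roi_name: str = "roi") -> dict[int, TSNRMask]:
    """The eight nested masks used to gate ROI pattern similarity."""
    return {p: threshold_by_percentile(tsnr_values, p, roi_name) for p in PERCENTILE_LEVELS}
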