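"""Annual-change-rate maps and the analysis mask.

Each subject's serial volume-change maps are reduced to a single per-voxel
annual rate by ordinary least squares of map value on acquisition time; the
fitted slope is the subject's atrophy-rate map. Rate maps are then smoothed
with an isotropic Gaussian kernel (default 8 mm FWHM) before any group
statistics. The analysis mask is built by averaging tissue-probability maps
across subjects and keeping voxels whose mean exceeds a threshold
(default 0.2, strict inequality).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import SubjectSeries
from .grid import Grid, fwhm_to_sigma_vox


@dataclass
class RateMap:
    """Per-voxel annual change rate (slope) for one subject."""

    subject_id: str
    data: np.ndarray
    grid: Grid
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.grid.check_data(self.data)


@dataclass
class AnalysisMask:
    """Boolean inclusion mask shared by all voxel-wise statistics."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.grid.check_data(self.data)
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def fit_voxel_slopes(series: SubjectSeries) -> RateMap:
    """OLS slope of map value on time, per voxel.

    With exactly two time points this reduces to the finite difference
    ``(map1 - map0) / (t1 - t0)``.
    """
    t = series.times
    if len(np.unique(t)) != len(t):
        raise ValueError("singular design: duplicate acquisition times")
    tc = t - t.mean()
    denom = float(np.sum(tc**2))
    stack = np.stack(series.maps, axis=0)  # (T, nx, ny, nz)
    slope = np.tensordot(tc, stack, axes=(0, 0)) / denom
    return RateMap(series.subject_id, slope, series.grid, group=series.group)


def smooth_map(data: np.ndarray, fwhm_mm: float, grid: Grid) -> np.ndarray:
    """Isotropic Gaussian smoothing; ``fwhm_mm == 0`` is the identity.

    Boundary handling is zero padding (no mask renormalisation): maps are
    smoothed whole, masks only enter at the statistics stage.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    data = grid.check_data(np.asarray(data, dtype=float))
    if fwhm_mm == 0:
        return data.copy()
    sigma = fwhm_to_sigma_vox(fwhm_mm, grid.voxel_size_mm)
    return gaussian_filter(data, sigma=sigma, mode="constant", cval=0.0)


def smooth_rate_map(rate_map: RateMap, fwhm_mm: float) -> RateMap:
    return RateMap(
        rate_map.subject_id,
        smooth_map(rate_map.data, fwhm_mm, rate_map.grid),
        rate_map.grid,
        group=rate_map.group,
    )


def build_mask(
    tissue_maps: list[np.ndarray], grid: Grid, threshold: float = 0.2
) -> AnalysisMask:
    """Mask of voxels whose mean tissue probability strictly exceeds `threshold`."""
    if not tissue_maps:
        raise ValueError("need at least one tissue map")
    stack = np.stack([grid.check_data(np.asarray(m, dtype=float)) for m in tissue_maps])
    if stack.min() < 0 or stack.max() > 1:
        raise ValueError("tissue probability values must lie in [0, 1]")
    mean = stack.mean(axis=0)
    mask = mean > threshold
    if not mask.any():
        raise ValueError("mask threshold excludes all voxels")
    return AnalysisMask(mask, grid)
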