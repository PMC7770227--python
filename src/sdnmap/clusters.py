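"""Residual smoothness estimation and Monte-Carlo cluster-extent inference.

Voxel-wise maps are thresholded at an uncorrected voxel p (default 0.005)
and clusters smaller than a simulated critical extent are discarded, so the
familywise error of reporting any noise-only cluster is controlled at the
cluster alpha (default 0.05). The critical extent is obtained by
simulation: Gaussian noise fields matched to the residual smoothness of
the fitted model are generated on the analysis mask, thresholded the same
way, and the (1 - alpha) quantile of the maximum cluster size is taken.

Smoothness is estimated with the classical Gaussian-field first-difference
estimator: along each axis,

    FWHM = d * sqrt(-2 ln 2 / ln(1 - var(diff) / (2 var)))

where d is the voxel size. Because a discrete lattice cannot resolve
smoothness below one voxel, estimates that would fall under one voxel are
floored at the voxel size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import Grid, fwhm_to_sigma_vox
from .glm import StatMap
from .rates import AnalysisMask

_LN2 = float(np.log(2.0))

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SmoothnessEstimate:
    """Per-axis and combined (geometric-mean) residual FWHM in mm."""

    fwhm_mm: tuple[float, float, float]
    voxel_size_mm: float

    @property
    def combined_mm(self) -> float:
        return float(np.prod(self.fwhm_mm) ** (1.0 / 3.0))

    @property
    def fwhm_vox(self) -> np.ndarray:
        return np.asarray(self.fwhm_mm) / self.voxel_size_mm


@dataclass
class ClusterThreshold:
    """Voxel-level threshold plus simulated minimum cluster extent."""

    voxel_p: float
    cluster_alpha: float
    min_extent_voxels: int
    n_simulations: int
    connectivity: int = 18

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1) or not (0 < self.cluster_alpha <= 1):
            raise ValueError("voxel_p and cluster_alpha must lie in (0, 1)")
        if self.min_extent_voxels < 1:
            raise ValueError("min_extent_voxels must be >= 1")


def _axis_fwhm(data: np.ndarray, mask: np.ndarray, axis: int, d: float) -> float:
    vals = data[mask]
    var = float(np.var(vals))
    if var <= 0:
        raise ValueError("flat residuals: zero variance inside mask")
    # first differences with both voxels inside the mask
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
    if not pair.any():
        raise ValueError(f"mask has no adjacent voxel pairs along axis {axis}")
    diffs = (data[tuple(sl_hi)] - data[tuple(sl_lo)])[pair]
    var_diff = float(np.var(diffs))
    arg = 1.0 - var_diff / (2.0 * var)
    # arg == exp(-2 ln 2) corresponds to FWHM == 1 voxel; floor below that
    if arg <= np.exp(-2.0 * _LN2):
        return d
    return d * float(np.sqrt(-2.0 * _LN2 / np.log(arg)))


def estimate_fwhm(
    residual_maps: list[np.ndarray], mask: AnalysisMask
) -> SmoothnessEstimate:
    """Average the per-axis first-difference FWHM estimator over maps."""
    if not residual_maps:
        raise ValueError("need at least one residual map")
    m = mask.data
    for axis in range(3):
        if mask.grid.shape[axis] < 2:
            raise ValueError("mask must span at least 2 voxels along each axis")
    d = mask.grid.voxel_size_mm
    per_map = np.array(
        [
            [_axis_fwhm(np.asarray(r, dtype=float), m, axis, d) for axis in range(3)]
            for r in residual_maps
        ]
    )
    fx, fy, fz = per_map.mean(axis=0)
    return SmoothnessEstimate((float(fx), float(fy), float(fz)), d)


def smooth_noise_field(
    rng: np.random.Generator, smoothness: SmoothnessEstimate, grid: Grid
) -> np.ndarray:
    """One Gaussian noise field with the given smoothness (unnormalised scale)."""
    sigmas = [
        fwhm_to_sigma_vox(f, 1.0)  # fwhm already in voxels after division
        for f in smoothness.fwhm_vox
    ]
    noise = rng.standard_normal(grid.shape)
    if any(s > 0 for s in sigmas):
        noise = ndimage.gaussian_filter(noise, sigma=sigmas, mode="constant", cval=0.0)
    return noise


def standardize_in_mask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = data[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero variance inside mask")
    return (data - vals.mean()) / sd


def simulate_cluster_threshold(
    smoothness: SmoothnessEstimate,
    mask: AnalysisMask,
    voxel_p: float = 0.005,
    cluster_alpha: float = 0.05,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
    connectivity: int = 18,
) -> ClusterThreshold:
    """Monte-Carlo critical cluster extent for smoothness-matched noise.

    Each simulation draws a Gaussian field at the estimated smoothness,
    standardises it within the mask, applies the two-sided voxel threshold
    and records the largest suprathreshold cluster. The minimum extent is
    the smallest k with P(max cluster >= k) <= cluster_alpha.
    """
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    if max(smoothness.fwhm_vox) > min(mask.grid.shape):
        raise ValueError("smoothing kernel larger than the grid")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.isf(voxel_p / 2.0)
    struct = CONNECTIVITY_STRUCTS[connectivity]
    m = mask.data
    maxima = np.empty(n_sim, dtype=int)
    for i in range(n_sim):
        field = smooth_noise_field(rng, smoothness, mask.grid)
        z = standardize_in_mask(field, m)
        supra = (np.abs(z) > z_crit) & m
        if not supra.any():
            maxima[i] = 0
            continue
        labels, n_lab = ndimage.label(supra, structure=struct)
        sizes = np.bincount(labels.ravel())[1:]
        maxima[i] = int(sizes.max())
    # smallest k with #(max >= k) <= alpha * n_sim
    allowed = int(np.floor(cluster_alpha * n_sim))
    if allowed >= n_sim:
        k = 1
    else:
        order = np.sort(maxima)
        k = int(order[n_sim - 1 - allowed]) + 1
    return ClusterThreshold(voxel_p, cluster_alpha, max(k, 1), n_sim, connectivity)


def _voxel_stat_threshold(stat_map: StatMap, voxel_p: float) -> float:
    if stat_map.stat_kind == "t":
        return float(stats.t.isf(voxel_p / 2.0, float(stat_map.df)))
    if stat_map.stat_kind == "z":
        return float(stats.norm.isf(voxel_p / 2.0))
    raise ValueError("cluster thresholding needs a t or z map")


def apply_cluster_threshold(
    stat_map: StatMap,
    threshold: ClusterThreshold,
    mask: AnalysisMask | None = None,
    two_sided: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Retain suprathreshold clusters with extent >= the simulated minimum.

    Returns the surviving binary map and a cluster table (one row per
    surviving cluster: label, size, peak statistic and peak voxel indices,
    ordered by size descending).
    """
    mask = mask or stat_map.mask
    if mask is None:
        raise ValueError("an analysis mask is required")
    crit = _voxel_stat_threshold(stat_map, threshold.voxel_p)
    data = np.nan_to_num(stat_map.data, nan=0.0)
    if two_sided:
        supra = (np.abs(data) > crit) & mask.data
    else:
        supra = (data > crit) & mask.data
    struct = CONNECTIVITY_STRUCTS[threshold.connectivity]
    surviving = np.zeros(mask.grid.shape, dtype=bool)
    rows = []
    if supra.any():
        labels, n_lab = ndimage.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            size = int(comp.sum())
            if size < threshold.min_extent_voxels:
                continue
            surviving |= comp
            vals = np.where(comp, data, 0.0)
            flat_peak = int(np.argmax(np.abs(vals)))
            i, j, k = np.unravel_index(flat_peak, mask.grid.shape)
            rows.append(
                {
                    "label": lab,
                    "size_voxels": size,
                    "peak_stat": float(data[i, j, k]),
                    "peak_i": int(i),
                    "peak_j": int(j),
                    "peak_k": int(k),
                }
            )
    table = pd.DataFrame(
        rows, columns=["label", "size_voxels", "peak_stat", "peak_i", "peak_j", "peak_k"]
    )
    if len(table):
        table = table.sort_values("size_voxels", ascending=False).reset_index(drop=True)
    return surviving, table
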