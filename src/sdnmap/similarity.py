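"""Spatial similarity with a smoothness-matched permutation null, and
goodness-of-fit (GOF) network preference.

Two maps are compared by the Pearson correlation of their in-mask voxel
values (unthresholded). Significance comes from a permutation null: the
SDN side is replaced by random Gaussian fields smoothed to the SDN map's
estimated residual smoothness, and the observed correlation is ranked
against the null correlations (two-sided on |r|, add-one rule, so p is
never exactly zero).

GOF measures how strongly a target z pattern concentrates inside a
binarized network: mean z inside minus mean z outside (within the mask).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import SmoothnessEstimate, smooth_noise_field, standardize_in_mask
from .glm import StatMap
from .networks import NetworkMask, top_percent_mask
from .rates import AnalysisMask


@dataclass
class SimilarityResult:
    """Observed spatial correlation, permutation null sample and p-value."""

    r_observed: float
    null_sample: np.ndarray
    p_perm: float
    n_perm: int


@dataclass
class GOFResult:
    """Mean z inside vs outside a network mask; gof = inside - outside."""

    mean_z_inside: float
    mean_z_outside: float
    network_size: int
    percent: float | None = None

    @property
    def gof(self) -> float:
        return self.mean_z_inside - self.mean_z_outside


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray, mask: AnalysisMask) -> float:
    """Pearson correlation of in-mask voxel values of two unthresholded maps."""
    a = np.asarray(map_a, dtype=float)[mask.data]
    b = np.asarray(map_b, dtype=float)[mask.data]
    if a.size < 3:
        raise ValueError("mask must contain at least 3 voxels")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("maps must be finite inside the mask")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance inside mask")
    return float(np.corrcoef(a, b)[0, 1])


def permutation_similarity(
    sdn_map: np.ndarray,
    target_map: np.ndarray,
    mask: AnalysisMask,
    smoothness: SmoothnessEstimate,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SimilarityResult:
    """Permutation test of spatial similarity against smoothness-matched noise.

    The null replaces the SDN map with `n_perm` Gaussian noise fields
    smoothed to the SDN's estimated smoothness and standardized within the
    mask; the target map stays fixed. p is two-sided on |r| with the
    add-one rule: ``(1 + #{|null| >= |r_obs|}) / (1 + n_perm)``.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    if max(smoothness.fwhm_vox) > min(mask.grid.shape):
        raise ValueError("smoothing kernel larger than the grid")
    r_obs = spatial_correlation(sdn_map, target_map, mask)
    rng = np.random.default_rng(seed)
    target = np.asarray(target_map, dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        field = smooth_noise_field(rng, smoothness, mask.grid)
        field = standardize_in_mask(field, mask.data)
        null[i] = spatial_correlation(field, target, mask)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(r_obs))) / (1.0 + n_perm)
    return SimilarityResult(r_obs, null, float(p), n_perm)


def gof(network: NetworkMask, target_zmap: np.ndarray, mask: AnalysisMask) -> GOFResult:
    """Goodness-of-fit of a network to a target z pattern (inside - outside)."""
    z = np.asarray(target_zmap, dtype=float)
    inside = network.data & mask.data
    outside = mask.data & ~network.data
    if not inside.any():
        raise ValueError("network has no voxels inside the mask")
    if not outside.any():
        raise ValueError("network covers the whole mask; outside set empty")
    zin = z[inside]
    zout = z[outside]
    if not (np.all(np.isfinite(zin)) and np.all(np.isfinite(zout))):
        raise ValueError("target map must be finite inside the mask")
    return GOFResult(
        float(zin.mean()), float(zout.mean()), int(inside.sum()), network.percent
    )


def gof_profile(
    sdn_zmap: StatMap,
    target_zmap: np.ndarray,
    mask: AnalysisMask,
    percents=tuple(range(1, 11)),
) -> list[GOFResult]:
    """GOF at a ladder of fixed-size top-percent networks (default 1..10%)."""
    results = []
    for p in percents:
        network = top_percent_mask(sdn_zmap, float(p), mask)
        results.append(gof(network, target_zmap, mask))
    return results
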