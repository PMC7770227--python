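"""Epicenter seeds and seed-based synchronized degeneration networks (SDNs).

An epicenter is the peak voxel of a surviving cluster in the
progression contrast (faster atrophy in progressing vs stable MCI). A
6-mm-radius sphere around it becomes a seed; each control subject's mean
atrophy rate inside the seed is then regressed against every voxel's rate
(with the usual nuisance covariates) to map which voxels degenerate in
synchrony with the seed — the SDN. Binarized network masks come either
from the cluster-FWE threshold or from a fixed-size top-percent cut.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import ClusterThreshold, apply_cluster_threshold
from .glm import StatMap, MassUnivariateGLM, make_seed_design, stack_in_mask, t_to_z, _embed
from .grid import Grid
from .rates import AnalysisMask, RateMap

logger = logging.getLogger(__name__)


@dataclass
class SphereSeed:
    """A spherical seed region: closed ball of `radius_mm` around a peak voxel."""

    center_ijk: tuple[int, int, int]
    radius_mm: float
    grid: Grid
    member_voxels: np.ndarray = field(init=False)  # (m, 3) int array

    def __post_init__(self) -> None:
        self.center_ijk = tuple(int(c) for c in self.center_ijk)
        if any(c < 0 or c >= s for c, s in zip(self.center_ijk, self.grid.shape)):
            raise ValueError("seed center outside grid")
        self.member_voxels = _sphere_members(self.center_ijk, self.radius_mm, self.grid)

    @property
    def center_mm(self) -> np.ndarray:
        return self.grid.voxel_to_mm(self.center_ijk)

    def mask_array(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        out[tuple(self.member_voxels.T)] = True
        return out


def _sphere_members(center: tuple[int, int, int], radius_mm: float, grid: Grid) -> np.ndarray:
    """Voxels whose center-to-center distance to `center` is <= radius_mm."""
    r_vox = radius_mm / grid.voxel_size_mm
    r_int = int(np.floor(r_vox))
    offs = np.arange(-r_int, r_int + 1)
    di, dj, dk = np.meshgrid(offs, offs, offs, indexing="ij")
    keep = di**2 + dj**2 + dk**2 <= r_vox**2 + 1e-12
    pts = np.column_stack([di[keep], dj[keep], dk[keep]]) + np.asarray(center)
    inside = np.all((pts >= 0) & (pts < np.asarray(grid.shape)), axis=1)
    return pts[inside].astype(int)


@dataclass
class NetworkMask:
    """Binarized SDN region set (cluster-thresholded or fixed-size)."""

    data: np.ndarray
    grid: Grid
    provenance: str  # "cluster_fwe_threshold" or "top_percent"
    percent: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.grid.check_data(self.data)
        if not self.data.any():
            raise ValueError("network mask is empty")

    @property
    def size_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SDNMap:
    """Seed-based coupling z-map and its binarized network."""

    seed: SphereSeed
    zmap: StatMap
    network: NetworkMask | None
    residual_maps: list[np.ndarray] | None = None


def find_epicenters(
    contrast_map: StatMap,
    cluster_table: pd.DataFrame,
    radius_mm: float = 6.0,
) -> list[SphereSeed]:
    """One sphere seed per surviving cluster, centered at its peak voxel.

    The cluster table is the output of
    :func:`sdnmap.clusters.apply_cluster_threshold`; peaks are by maximal
    |statistic| with ties broken by smallest flat scan-order index (the
    ordering the labeling pass itself produces).
    """
    if cluster_table is None or len(cluster_table) == 0:
        raise ValueError("no epicenters at current threshold: no surviving clusters")
    seeds = []
    for _, row in cluster_table.iterrows():
        center = (int(row["peak_i"]), int(row["peak_j"]), int(row["peak_k"]))
        seeds.append(SphereSeed(center, radius_mm, contrast_map.grid))
    return seeds


def extract_seed_rate(rate_map: RateMap, seed: SphereSeed, mask: AnalysisMask | None = None) -> float:
    """Unweighted mean rate over the seed's member voxels (optionally in-mask)."""
    pts = seed.member_voxels
    if mask is not None:
        keep = mask.data[tuple(pts.T)]
        pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("seed has no member voxels inside the mask")
    return float(rate_map.data[tuple(pts.T)].mean())


def map_sdn(
    hc_rate_maps: list[RateMap],
    seed_values: np.ndarray,
    cov_df: pd.DataFrame,
    mask: AnalysisMask,
    seed: SphereSeed,
    threshold: ClusterThreshold | None = None,
    two_sided: bool = False,
) -> SDNMap:
    """Seed-coupling GLM across control subjects, z-converted and binarized.

    Per voxel, the rate is regressed on the seed value plus nuisance
    covariates; the seed regressor's t is converted to z. When a
    :class:`ClusterThreshold` is given, the network mask keeps clusters of
    positively coupled voxels (``two_sided=False``, the default, since
    synchronized degeneration is positive covariance) that pass the
    cluster-FWE criterion.
    """
    seed_values = np.asarray(seed_values, dtype=float)
    if len(hc_rate_maps) != len(seed_values) or len(seed_values) != len(cov_df):
        raise ValueError("rate maps, seed values and covariates must align")
    if len(hc_rate_maps) < len(cov_df.columns) + 2:
        raise ValueError("too few subjects for the seed GLM")
    design = make_seed_design(seed_values, cov_df)
    Y = stack_in_mask(hc_rate_maps, mask)
    model = MassUnivariateGLM(column_names=design.names).fit(design.matrix, Y)
    t = model.t_contrast(design.contrast("seed"))
    tmap = StatMap(_embed(t, mask), "t", model.df_resid_, "sdn:seed-coupling", mask.grid, mask)
    zmap = t_to_z(tmap)
    network = None
    if threshold is not None:
        surviving, _ = apply_cluster_threshold(zmap, threshold, mask, two_sided=two_sided)
        if surviving.any():
            network = NetworkMask(surviving, mask.grid, "cluster_fwe_threshold")
        else:
            logger.warning("SDN network empty at the cluster-FWE threshold")
    residuals = [_embed(model.residuals_[i], mask) for i in range(len(hc_rate_maps))]
    return SDNMap(seed, zmap, network, residuals)


def top_percent_mask(
    sdn_zmap: StatMap, percent: float, mask: AnalysisMask | None = None
) -> NetworkMask:
    """Fixed-size network: the top `percent` of in-mask voxels by z value.

    Retains ``ceil(percent/100 * n_mask_voxels)`` voxels ranked by z
    descending; ties at the cut are broken by scan order (stable sort).
    """
    mask = mask or sdn_zmap.mask
    if mask is None:
        raise ValueError("an analysis mask is required")
    if not (0 < percent <= 100):
        raise ValueError("percent must lie in (0, 100]")
    m = mask.data
    z = sdn_zmap.data[m]
    n_keep = int(np.ceil(percent / 100.0 * z.size))
    order = np.argsort(-z, kind="stable")[:n_keep]
    flat_idx = np.flatnonzero(m.ravel())[order]
    out = np.zeros(mask.grid.n_voxels, dtype=bool)
    out[flat_idx] = True
    return NetworkMask(out.reshape(mask.grid.shape), mask.grid, "top_percent", percent)
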