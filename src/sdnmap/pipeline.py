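"""End-to-end orchestration of the SDN analysis.

Stages, in order: (A) obtain the cohort (simulated or read from disk);
(B) per-subject annual rate maps, smoothed, plus the analysis mask;
(C) group ANCOVA on the progression contrast, cluster-FWE thresholding and
epicenter seeds; (D) seed-based SDN mapping in controls with cluster-FWE
binarization; (E) per-group one-sample degeneration z maps (atrophy mapped
to positive z); (F) permutation spatial similarity, goodness-of-fit
profiles, and the cognitive-decline association.

All stochastic stages draw from one seeded generator hierarchy recorded in
the run manifest, so a rerun with the same config reproduces every output.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GROUPS, covariate_table
from .cognition import bonferroni, cognitive_slopes, partial_spearman
from .clusters import (
    ClusterThreshold,
    SmoothnessEstimate,
    apply_cluster_threshold,
    estimate_fwhm,
    simulate_cluster_threshold,
)
from .glm import fit_ancova, fit_one_sample, make_ancova_design, t_to_z
from .networks import NetworkMask, SDNMap, extract_seed_rate, find_epicenters, map_sdn
from .rates import AnalysisMask, build_mask, fit_voxel_slopes, smooth_rate_map
from .similarity import gof, gof_profile, permutation_similarity
from .synthetic import default_cohort_spec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the standard analysis settings:
    8 mm smoothing, 0.2 mask threshold, voxel p<0.005 with cluster-FWE
    p<0.05, 6-mm seed spheres, 1000 permutations, Bonferroni over 6 tests.
    """

    input_dir: str | None = None  # None -> simulate the default synthetic cohort
    fwhm_mm: float = 8.0
    mask_threshold: float = 0.2
    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    connectivity: int = 18
    n_cluster_sim: int = 1000
    seed_radius_mm: float = 6.0
    n_perm: int = 1000
    gof_percents: tuple = tuple(range(1, 11))
    bonferroni_alpha: float = 0.05
    bonferroni_n: int = 6
    progression_contrast: str = "MCIs-MCIp"  # positive t = faster atrophy in MCIp
    patient_groups: tuple = ("MCIs", "MCIp", "AD")
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimilarityRow:
    sdn_name: str
    group: str
    r_observed: float
    p_perm: float


@dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    config: PipelineConfig
    mask: AnalysisMask
    rate_maps: list
    contrast_map: object
    cluster_threshold: ClusterThreshold
    cluster_table: pd.DataFrame
    seeds: list
    sdn_maps: dict  # name -> SDNMap
    group_zmaps: dict  # group -> StatMap (atrophy positive)
    similarity: pd.DataFrame
    gof_table: pd.DataFrame
    gof_profile_table: pd.DataFrame
    cognition: dict  # sdn name -> DataFrame
    network_rates: pd.DataFrame  # subjects x SDN names
    manifest: dict
    truth: object = None


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    names = ["cohort", "cluster_sim", "sdn_sim", "permutation"]
    children = ss.spawn(len(names))
    return {nm: int(ch.generate_state(1, np.uint32)[0] % (2**31)) for nm, ch in zip(names, children)}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    cohort=None,
) -> PipelineResult:
    """Execute stages A-F; optionally write all artifacts under ``out_dir``.

    ``cohort`` may be a pre-built ``(subjects, records, truth)`` triple to
    bypass stage A (used heavily in testing).
    """
    seeds = _stage_seeds(config.seed)
    truth = None

    # --- A: cohort -----------------------------------------------------
    if cohort is not None:
        subjects, records, truth = cohort
    elif config.input_dir is not None:
        from .io import read_cohort

        try:
            subjects, records = read_cohort(config.input_dir)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage A (cohort): missing input file: {exc}") from exc
    else:
        spec = default_cohort_spec(seed=seeds["cohort"])
        subjects, records, truth = generate_cohort(spec)
    if not subjects:
        raise RuntimeError("stage A (cohort): no subjects")
    grid = subjects[0].grid
    cov_df = covariate_table(subjects)

    # --- B: rate maps and mask ----------------------------------------
    rate_maps = [smooth_rate_map(fit_voxel_slopes(s), config.fwhm_mm) for s in subjects]
    if truth is not None:
        mask = build_mask([truth.spec.tissue_probability()], grid, config.mask_threshold)
    else:
        # without tissue maps: voxels with non-zero baseline signal
        baseline = np.mean([np.abs(s.maps[0]) > 1e-6 for s in subjects], axis=0)
        mask = build_mask([baseline], grid, config.mask_threshold)

    by_group = {g: [rm for rm in rate_maps if rm.group == g] for g in GROUPS}
    cov_by_group = {g: cov_df[cov_df["group"] == g] for g in GROUPS}

    # --- C: progression contrast, cluster inference, epicenters --------
    design = make_ancova_design(cov_df)
    tmap, model = fit_ancova(rate_maps, design, config.progression_contrast, mask, return_model=True)
    from .glm import residual_rate_maps

    residuals = residual_rate_maps(model, mask)
    smoothness = estimate_fwhm(residuals, mask)
    threshold = simulate_cluster_threshold(
        smoothness,
        mask,
        voxel_p=config.voxel_p,
        cluster_alpha=config.cluster_alpha,
        n_sim=config.n_cluster_sim,
        seed=seeds["cluster_sim"],
        connectivity=config.connectivity,
    )
    zmap = t_to_z(tmap)
    # one-sided: epicenters are where atrophy is faster in the progressing group
    surviving, cluster_table = apply_cluster_threshold(zmap, threshold, mask, two_sided=False)
    seeds_list = find_epicenters(zmap, cluster_table, config.seed_radius_mm)

    # --- D: SDNs in controls -------------------------------------------
    hc_rates = by_group["HC"]
    hc_cov = cov_by_group["HC"].drop(columns="group")
    sdn_maps: dict[str, SDNMap] = {}
    sdn_smoothness: dict[str, SmoothnessEstimate] = {}
    rng_sdn = np.random.default_rng(seeds["sdn_sim"])
    for idx, seed_roi in enumerate(seeds_list):
        name = f"sdn{idx:02d}"
        seed_vals = np.array([extract_seed_rate(rm, seed_roi, mask) for rm in hc_rates])
        sdn = map_sdn(hc_rates, seed_vals, hc_cov, mask, seed_roi, threshold=None)
        sm = estimate_fwhm(sdn.residual_maps, mask)
        thr = simulate_cluster_threshold(
            sm,
            mask,
            voxel_p=config.voxel_p,
            cluster_alpha=config.cluster_alpha,
            n_sim=config.n_cluster_sim,
            seed=int(rng_sdn.integers(2**31)),
            connectivity=config.connectivity,
        )
        surviving_sdn, _ = apply_cluster_threshold(sdn.zmap, thr, mask, two_sided=False)
        if surviving_sdn.any():
            sdn.network = NetworkMask(surviving_sdn, grid, "cluster_fwe_threshold")
        sdn_maps[name] = sdn
        sdn_smoothness[name] = sm

    # --- E: group degeneration z maps (atrophy positive) ---------------
    group_zmaps = {}
    for g in config.patient_groups:
        if not by_group[g]:
            continue
        t_g = fit_one_sample(by_group[g], cov_by_group[g].drop(columns="group"), mask)
        z_g = t_to_z(t_g)
        z_g.data = -z_g.data  # decline (negative rate) mapped to positive z
        z_g.contrast = f"one-sample:{g}:atrophy-positive"
        group_zmaps[g] = z_g

    # --- F: similarity, GOF, cognition ---------------------------------
    rng_perm = np.random.default_rng(seeds["permutation"])
    sim_rows, gof_rows, prof_rows = [], [], []
    for name, sdn in sdn_maps.items():
        for g, z_g in group_zmaps.items():
            res = permutation_similarity(
                sdn.zmap.data,
                z_g.data,
                mask,
                sdn_smoothness[name],
                n_perm=config.n_perm,
                seed=int(rng_perm.integers(2**31)),
            )
            sim_rows.append(
                {"sdn": name, "group": g, "r_observed": res.r_observed, "p_perm": res.p_perm}
            )
            if sdn.network is not None:
                g_res = gof(sdn.network, z_g.data, mask)
                gof_rows.append(
                    {
                        "sdn": name,
                        "group": g,
                        "gof": g_res.gof,
                        "mean_z_inside": g_res.mean_z_inside,
                        "mean_z_outside": g_res.mean_z_outside,
                        "network_size": g_res.network_size,
                    }
                )
            for g_res in gof_profile(sdn.zmap, z_g.data, mask, config.gof_percents):
                prof_rows.append(
                    {"sdn": name, "group": g, "percent": g_res.percent, "gof": g_res.gof}
                )

    slopes = cognitive_slopes(records)
    net_rate_rows = {}
    for name, sdn in sdn_maps.items():
        if sdn.network is None:
            continue
        net_rate_rows[name] = {
            rm.subject_id: float(rm.data[sdn.network.data & mask.data].mean()) for rm in rate_maps
        }
    network_rates = pd.DataFrame(net_rate_rows)
    cognition = {}
    cov_mat = cov_df[["age", "sex", "education", "tiv"]].to_numpy(dtype=float)
    for name in network_rates.columns:
        results = []
        for test in slopes.columns:
            joined = pd.concat([network_rates[name], slopes[test]], axis=1, join="inner").dropna()
            if np.ptp(joined.iloc[:, 1].to_numpy()) == 0:
                logger.info("skipping %s: constant slopes", test)
                continue
            common = joined.index
            covs = cov_df.loc[common, ["age", "sex", "education", "tiv"]].to_numpy(dtype=float)
            res = partial_spearman(
                joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy(), covs, test_name=test
            )
            results.append(res)
        annotated = bonferroni(results, config.bonferroni_alpha, config.bonferroni_n)
        cognition[name] = pd.DataFrame(
            [
                {
                    "test_name": r.test_name,
                    "rho": r.rho,
                    "p": r.p,
                    "alpha_threshold": r.alpha_threshold,
                    "significant": r.significant,
                }
                for r in annotated
            ]
        )

    manifest = {
        "software": {"name": "sdnmap", "version": __version__},
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_subjects": len(subjects),
        "mask_voxels": mask.n_voxels,
        "smoothness_fwhm_mm": list(smoothness.fwhm_mm),
        "cluster_min_extent": threshold.min_extent_voxels,
        "epicenters_ijk": [list(s.center_ijk) for s in seeds_list],
    }

    result = PipelineResult(
        config=config,
        mask=mask,
        rate_maps=rate_maps,
        contrast_map=zmap,
        cluster_threshold=threshold,
        cluster_table=cluster_table,
        seeds=seeds_list,
        sdn_maps=sdn_maps,
        group_zmaps=group_zmaps,
        similarity=pd.DataFrame(sim_rows),
        gof_table=pd.DataFrame(gof_rows),
        gof_profile_table=pd.DataFrame(prof_rows),
        cognition=cognition,
        network_rates=network_rates,
        manifest=manifest,
        truth=truth,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    from .io import save_map

    out.mkdir(parents=True, exist_ok=True)
    grid = result.mask.grid
    save_map(result.mask.data.astype(np.float32), grid, out / "analysis_mask.nii.gz")
    save_map(np.nan_to_num(result.contrast_map.data), grid, out / "contrast_z.nii.gz")
    result.cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    for name, sdn in result.sdn_maps.items():
        save_map(np.nan_to_num(sdn.zmap.data), grid, out / f"{name}_z.nii.gz")
        if sdn.network is not None:
            save_map(sdn.network.data.astype(np.float32), grid, out / f"{name}_network.nii.gz")
    for g, z in result.group_zmaps.items():
        save_map(np.nan_to_num(z.data), grid, out / f"group_{g}_z.nii.gz")
    result.similarity.to_csv(out / "similarity.tsv", sep="\t", index=False)
    result.gof_table.to_csv(out / "gof.tsv", sep="\t", index=False)
    result.gof_profile_table.to_csv(out / "gof_profile.tsv", sep="\t", index=False)
    if len(result.network_rates):
        result.network_rates.to_csv(out / "network_rates.tsv", sep="\t")
    report = {
        "similarity": result.similarity.to_dict(orient="records"),
        "gof": result.gof_table.to_dict(orient="records"),
        "cognition": {k: v.to_dict(orient="records") for k, v in result.cognition.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
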