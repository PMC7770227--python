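"""Disk formats: NIfTI-1 for maps, TSV for tables, JSON for reports.

File layout for a cohort directory::

    maps/<subject>_tp<k>.nii.gz     serial volume-change maps
    tissue/<subject>.nii.gz         tissue-probability map (optional)
    covariates.tsv                  subject_id, group, age, sex, education, tiv
    cognitive_scores.tsv            subject_id, test_name, time_years, score
    ground_truth.json (+ truth_*.nii.gz)   synthetic cohorts only
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CognitiveRecord, SubjectSeries
from .grid import Grid


def save_map(data: np.ndarray, grid: Grid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms((grid.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def load_map(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic voxels {zooms} are not supported")
    return data, Grid(tuple(data.shape), float(zooms[0]))


def write_cohort(
    subjects: list[SubjectSeries],
    records: list[CognitiveRecord],
    out_dir: str | Path,
    truth=None,
) -> Path:
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    cov_rows = []
    for s in subjects:
        for k, (t, m) in enumerate(zip(s.times, s.maps)):
            save_map(m, s.grid, out / "maps" / f"{s.subject_id}_tp{k}.nii.gz")
        cov_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "times_years": ",".join(f"{t:.6g}" for t in s.times),
                **s.covariates,
            }
        )
    pd.DataFrame(cov_rows).to_csv(out / "covariates.tsv", sep="\t", index=False)

    score_rows = [
        {"subject_id": r.subject_id, "test_name": r.test_name, "time_years": t, "score": sc}
        for r in records
        for t, sc in zip(r.times, r.scores)
    ]
    pd.DataFrame(score_rows).to_csv(out / "cognitive_scores.tsv", sep="\t", index=False)

    if truth is not None:
        for name, m in truth.network_masks.items():
            save_map(m.astype(np.float32), truth.spec.grid, out / f"truth_network_{name}.nii.gz")
        sidecar = {
            "epicenters_ijk": {k: list(v) for k, v in truth.epicenters.items()},
            "factors": {c: truth.factors[c].round(10).to_dict() for c in truth.factors},
            "network_rate": truth.network_rate.round(10).to_dict(),
            "cognitive_slopes": {
                c: truth.cognitive_slopes[c].round(10).to_dict() for c in truth.cognitive_slopes
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectSeries], list[CognitiveRecord]]:
    in_dir = Path(in_dir)
    cov = pd.read_csv(in_dir / "covariates.tsv", sep="\t", dtype={"subject_id": str})
    subjects = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        times = np.array([float(x) for x in str(row["times_years"]).split(",")])
        maps, grid = [], None
        for k in range(len(times)):
            data, grid = load_map(in_dir / "maps" / f"{sid}_tp{k}.nii.gz")
            maps.append(data)
        subjects.append(
            SubjectSeries(
                sid,
                row["group"],
                {c: float(row[c]) for c in ("age", "sex", "education", "tiv")},
                times,
                maps,
                grid,
            )
        )
    records = []
    score_path = in_dir / "cognitive_scores.tsv"
    if score_path.exists():
        scores = pd.read_csv(score_path, sep="\t", dtype={"subject_id": str})
        for (sid, test), g in scores.groupby(["subject_id", "test_name"], sort=True):
            g = g.sort_values("time_years")
            if len(g) < 2:
                continue
            records.append(
                CognitiveRecord(sid, test, g["time_years"].to_numpy(), g["score"].to_numpy())
            )
    return subjects, records
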