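"""Readers and writers: NIfTI volumes, SPM-style realignment text, TSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthgen import CohortData, RealignmentParams, VolumeSeries

__all__ = [
    "read_volume",
    "write_volume",
    "read_realignment",
    "write_realignment",
    "write_cohort",
    "read_covariates",
    "write_covariates",
]


def write_volume(series: VolumeSeries, path: str | Path) -> Path:
    """Write a 4D series as NIfTI-1; voxel size goes in the spatial zooms and
    the repetition time in the 4th zoom."""
    path = Path(path)
    affine = np.diag([*series.voxel_mm, 1.0])
    img = nib.Nifti1Image(series.intensities, affine)
    img.header.set_zooms((*series.voxel_mm, series.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VolumeSeries:
    """Read a 4D NIfTI-1 file back into a :class:`VolumeSeries`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()
    voxel_mm = tuple(float(z) for z in zooms[:3])
    tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return VolumeSeries(data, voxel_mm, tr_s)


def write_realignment(realign: RealignmentParams, path: str | Path) -> Path:
    """Whitespace-delimited 6-column text file (SPM rp_*.txt dialect)."""
    path = Path(path)
    np.savetxt(path, realign.values, fmt="%.10e")
    return path


def read_realignment(path: str | Path) -> RealignmentParams:
    values = np.loadtxt(path)
    return RealignmentParams(np.atleast_2d(values))


def write_covariates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Write each subject as NIfTI + rp text, plus a cohort covariate TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        write_volume(subj.volume, out_dir / f"{subj.subject_id}_bold.nii.gz")
        write_realignment(subj.realignment, out_dir / f"rp_{subj.subject_id}.txt")
        rows.append({
            "subject_id": subj.subject_id, "group": subj.group,
            "age": subj.age, "gender": subj.gender, "pair_id": subj.pair_id,
        })
    write_covariates(pd.DataFrame(rows), out_dir / "participants.tsv")
    return out_dir
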