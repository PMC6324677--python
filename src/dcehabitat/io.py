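"""Standard-format I/O: NIfTI volumes, CSV tables, JSON sidecars.

A patient on disk is a directory holding ``dce.nii.gz`` (4-D), ``adc.nii.gz``,
one ``mask_<name>.nii.gz`` per mask, a ``biopsies.csv`` table, a ``meta.json``
with the acquisition geometry/timing and, for synthetic patients, a
``truth.json`` ground-truth sidecar.  All writes are atomic (temp file +
rename).  The NIfTI affine is diagonal in the voxel spacing with origin 0,
so world coordinates in mm are voxel index times spacing.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import BiExpFit
from .preprocess import DCESeries
from .synthetic import BiopsySample, LesionTruth, SyntheticPatient

__all__ = ["write_patient", "read_patient", "write_results", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes of one patient disagree on their voxel grid."""


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _atomic_save_nifti(img: nib.Nifti1Image, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".nii.gz")
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _atomic_write_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_patient(patient: SyntheticPatient, out_dir: str | Path) -> Path:
    """Write one patient bundle; returns the patient directory."""
    pdir = Path(out_dir) / patient.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    spacing = patient.dce.voxel_spacing
    aff = _affine(spacing)
    _atomic_save_nifti(
        nib.Nifti1Image(patient.dce.intensities.astype(np.float32), aff),
        pdir / "dce.nii.gz")
    _atomic_save_nifti(
        nib.Nifti1Image(patient.adc.astype(np.float32), aff),
        pdir / "adc.nii.gz")
    for name, mask in patient.masks.items():
        _atomic_save_nifti(
            nib.Nifti1Image(mask.astype(np.uint8), aff),
            pdir / f"mask_{name}.nii.gz")
    biopsy_df = pd.DataFrame([asdict(b) for b in patient.biopsies])
    _atomic_write_text(biopsy_df.to_csv(index=False), pdir / "biopsies.csv")
    meta = {
        "patient_id": patient.patient_id,
        "times_s": patient.dce.times.tolist(),
        "voxel_spacing_mm": list(spacing),
        "temporal_resolution_s": patient.dce.temporal_resolution,
        "pre_contrast_frames": patient.dce.pre_contrast_frames,
        "motion_artifact": patient.motion_artifact,
    }
    _atomic_write_text(json.dumps(meta, indent=2), pdir / "meta.json")
    if patient.truth:
        truth = [
            {**asdict(t), "params": asdict(t.params)} for t in patient.truth
        ]
        _atomic_write_text(json.dumps(truth, indent=2), pdir / "truth.json")
    return pdir


def read_patient(patient_dir: str | Path) -> SyntheticPatient:
    """Read a patient bundle back, validating that all grids match."""
    pdir = Path(patient_dir)
    meta = json.loads((pdir / "meta.json").read_text())
    dce_img = nib.load(pdir / "dce.nii.gz")
    dce_data = np.asarray(dce_img.dataobj, dtype=float)
    if dce_data.ndim != 4:
        raise GridMismatchError(f"dce.nii.gz must be 4-D, got shape {dce_data.shape}")
    grid = dce_data.shape[:3]
    adc = np.asarray(nib.load(pdir / "adc.nii.gz").dataobj, dtype=float)
    if adc.shape != grid:
        raise GridMismatchError(f"ADC grid {adc.shape} does not match DCE grid {grid}")
    masks: dict[str, np.ndarray] = {}
    for mpath in sorted(pdir.glob("mask_*.nii.gz")):
        name = mpath.name[len("mask_"):-len(".nii.gz")]
        m = np.asarray(nib.load(mpath).dataobj)
        if m.shape != grid:
            raise GridMismatchError(
                f"mask {name!r} grid {m.shape} does not match DCE grid {grid}")
        masks[name] = m.astype(bool)
    biopsies = []
    bio_path = pdir / "biopsies.csv"
    if bio_path.exists() and bio_path.stat().st_size > 0:
        for _, row in pd.read_csv(bio_path).iterrows():
            biopsies.append(BiopsySample(
                biopsy_id=str(row["biopsy_id"]), patient_id=str(row["patient_id"]),
                x_mm=float(row["x_mm"]), y_mm=float(row["y_mm"]),
                z_mm=float(row["z_mm"]),
                gleason_primary=int(row["gleason_primary"]),
                gleason_secondary=int(row["gleason_secondary"]),
                lesion_index=int(row["lesion_index"]),
            ))
    truth: list[LesionTruth] = []
    truth_path = pdir / "truth.json"
    if truth_path.exists():
        for t in json.loads(truth_path.read_text()):
            params = {k: v for k, v in t["params"].items()
                      if k in ("s0", "A", "t0", "k_in", "k_out", "residual_pct",
                               "degenerate", "flags")}
            truth.append(LesionTruth(
                lesion_index=t["lesion_index"], significant=t["significant"],
                center_mm=tuple(t["center_mm"]), radius_mm=t["radius_mm"],
                params=BiExpFit(**params), adc_level=t["adc_level"],
                dominant_zone=t["dominant_zone"],
            ))
    series = DCESeries(
        intensities=dce_data,
        times=np.asarray(meta["times_s"], dtype=float),
        voxel_spacing=tuple(meta["voxel_spacing_mm"]),
        temporal_resolution=float(meta["temporal_resolution_s"]),
        pre_contrast_frames=int(meta["pre_contrast_frames"]),
    )
    return SyntheticPatient(
        patient_id=meta["patient_id"], dce=series, adc=adc, masks=masks,
        biopsies=biopsies, truth=truth,
        motion_artifact=bool(meta.get("motion_artifact", False)),
    )


def write_results(results: dict, out_dir: str | Path) -> Path:
    """Write pipeline result tables/JSON atomically; returns the directory.

    ``results`` maps output names to pandas DataFrames (written as CSV) or
    JSON-serialisable objects (written as .json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            _atomic_write_text(obj.to_csv(index=False), out / f"{name}.csv")
        else:
            _atomic_write_text(json.dumps(obj, indent=2, default=_json_default),
                               out / f"{name}.json")
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
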