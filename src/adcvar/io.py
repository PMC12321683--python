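"""NIfTI / CSV persistence for cohorts and ADC maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import ADCMap, BValueSet
from .synthetic import MANIFEST_COLUMNS, AcquisitionParams, SyntheticScan


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_volume(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def write_scan(scan: SyntheticScan, scan_dir: Path, root=None) -> dict[str, str]:
    """Write a scan's DWI stack (one NIfTI per b-value) and masks.

    Returns the path fields for the manifest row, relative to ``root``
    when given (so output directories are relocatable).  Scans without
    DWI produce no files and blank paths.
    """
    paths = {
        "dwi_path": "",
        "tumor_mask_path": "",
        "exclusion_mask_path": "",
        "muscle_mask_path": "",
    }
    if scan.dwi is None:
        return paths

    def rel(p: Path) -> str:
        return str(p.relative_to(root)) if root is not None else str(p)

    scan_dir = Path(scan_dir)
    scan_dir.mkdir(parents=True, exist_ok=True)
    vs = scan.voxel_size_mm
    for b, vol in zip(scan.bvalues, scan.dwi):
        save_volume(scan_dir / f"b{int(round(b))}.nii.gz", vol, vs)
    paths["dwi_path"] = rel(scan_dir)
    save_volume(scan_dir / "tumor_mask.nii.gz", scan.tumor_mask.astype(np.uint8), vs)
    paths["tumor_mask_path"] = rel(scan_dir / "tumor_mask.nii.gz")
    save_volume(
        scan_dir / "exclusion_mask.nii.gz", scan.exclusion_mask.astype(np.uint8), vs
    )
    paths["exclusion_mask_path"] = rel(scan_dir / "exclusion_mask.nii.gz")
    if scan.muscle_mask is not None:
        save_volume(scan_dir / "muscle_mask.nii.gz", scan.muscle_mask.astype(np.uint8), vs)
        paths["muscle_mask_path"] = rel(scan_dir / "muscle_mask.nii.gz")
    return paths


def load_scan(row: pd.Series, root=".") -> SyntheticScan:
    """Rebuild a scan (without ground truth) from a manifest row."""
    root = Path(root)
    bvalues = tuple(float(v) for v in str(row["bvalues"]).split(";"))
    dwi = tumor = excl = muscle = None
    if row["dwi_path"]:
        scan_dir = root / row["dwi_path"]
        dwi = np.stack(
            [load_volume(scan_dir / f"b{int(round(b))}.nii.gz") for b in bvalues]
        )
        tumor = load_volume(root / row["tumor_mask_path"]) > 0.5
        excl = load_volume(root / row["exclusion_mask_path"]) > 0.5
        if isinstance(row["muscle_mask_path"], str) and row["muscle_mask_path"]:
            muscle = load_volume(root / row["muscle_mask_path"]) > 0.5

    def _opt(name):
        v = row.get(name)
        return None if pd.isna(v) else float(v)

    acq = AcquisitionParams(
        te_ms=_opt("te_ms"),
        pixel_spacing_mm=_opt("pixel_spacing_mm"),
        slice_thickness_mm=_opt("slice_thickness_mm"),
        n_bvalues=None if pd.isna(row.get("n_bvalues")) else int(row["n_bvalues"]),
        highest_bvalue=_opt("highest_bvalue"),
    )
    return SyntheticScan(
        scan_id=row["scan_id"],
        patient_id=row["patient_id"],
        center_id=row["center_id"],
        timepoint=row["timepoint"],
        acquisition=acq,
        bvalues=bvalues,
        dwi=dwi,
        tumor_mask=tumor,
        exclusion_mask=excl,
        muscle_mask=muscle,
        quality_score=int(row["quality_score"]),
        has_dwi=bool(row["has_dwi"]),
        has_measurable_tumor=bool(row["has_measurable_tumor"]),
        in_fov=bool(row["in_fov"]),
    )


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "scan_id": str,
            "patient_id": str,
            "center_id": str,
            "timepoint": str,
        },
        keep_default_na=True,
    )
    for col in ("dwi_path", "tumor_mask_path", "exclusion_mask_path", "muscle_mask_path"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def save_adc_map(adc_map: ADCMap, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """ADC NIfTI plus a JSON sidecar recording the fitted b-values."""
    path = Path(path)
    save_volume(path, np.nan_to_num(adc_map.adc, nan=-1.0), voxel_size)
    sidecar = path.with_name(path.name.replace(".nii.gz", "") + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"fit_bvalues": list(adc_map.fit_bvalues.values), "invalid_value": -1.0},
            fh,
            indent=2,
        )


def load_adc_map(path) -> ADCMap:
    path = Path(path)
    data = load_volume(path)
    sidecar = path.with_name(path.name.replace(".nii.gz", "") + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    invalid = data == meta.get("invalid_value", -1.0)
    adc = data.copy()
    adc[invalid] = np.nan
    return ADCMap(adc=adc, fit_bvalues=BValueSet.coerce(meta["fit_bvalues"]), invalid_mask=invalid)
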