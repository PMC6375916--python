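"""File formats: NIfTI images and maps, subjects CSV, reports, ROI volumes.

Image stacks travel as NIfTI-1 with the spin-lock times in a JSON sidecar
(``<stem>.json`` next to the image); pixel spacing rides in the NIfTI
header zooms.  Subject tables use a fixed CSV schema and are validated on
read with explicit error messages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CIRRHOSIS, NO_CIRRHOSIS, SUBJECT_COLUMNS
from .diagnostics import DiagnosticReport, RocCurve
from .relaxometry import SpinLockSeries, T1RhoMapResults
from .roi import Roi, RoiSet

_NUMERIC_COLUMNS = ["t1rho_croi_ms", "t1rho_wl_ms", "re", "ffq_ms"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def _affine(pixel_spacing_mm: float | None) -> np.ndarray:
    sp = pixel_spacing_mm or 1.0
    return np.diag([sp, sp, 1.0, 1.0])


def save_series(series: SpinLockSeries, path: str | Path) -> Path:
    """Write a spin-lock series as a 3D NIfTI (T_SL on the last axis) + sidecar."""
    path = Path(path)
    data = np.moveaxis(series.images, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.pixel_spacing_mm))
    nib.save(img, path)
    sidecar = {
        "spin_lock_times_ms": [float(t) for t in series.spin_lock_times],
        "slice_id": series.slice_id,
        "pixel_spacing_mm": series.pixel_spacing_mm,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_series(path: str | Path, spin_lock_times=None) -> SpinLockSeries:
    """Read a series written by :func:`save_series` (or any 3D NIfTI plus
    an explicit list of spin-lock times)."""
    path = Path(path)
    img = nib.load(path)
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    slice_id = ""
    spacing = float(img.header.get_zooms()[0])
    sidecar = _sidecar_path(path)
    if spin_lock_times is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no spin-lock times given and sidecar {sidecar} not found"
            )
        meta = json.loads(sidecar.read_text())
        spin_lock_times = meta["spin_lock_times_ms"]
        slice_id = meta.get("slice_id", "")
        spacing = meta.get("pixel_spacing_mm") or spacing
    return SpinLockSeries(
        images=data,
        spin_lock_times=np.asarray(spin_lock_times, dtype=float),
        slice_id=slice_id,
        pixel_spacing_mm=spacing,
    )


def save_image(image: np.ndarray, path: str | Path, pixel_spacing_mm: float | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), _affine(pixel_spacing_mm)), path)
    return path


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj, dtype=float)


def save_map(results: T1RhoMapResults, prefix: str | Path) -> dict[str, Path]:
    """Write a fitted map as ``<prefix>_t1rho.nii`` + ``<prefix>_valid.nii``
    (0/1) + ``<prefix>_summary.json``; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "t1rho": prefix.with_name(prefix.name + "_t1rho.nii"),
        "valid": prefix.with_name(prefix.name + "_valid.nii"),
        "summary": prefix.with_name(prefix.name + "_summary.json"),
    }
    save_image(np.nan_to_num(results.t1rho, nan=0.0), paths["t1rho"], results.pixel_spacing_mm)
    save_image(results.valid_mask.astype(np.float64), paths["valid"], results.pixel_spacing_mm)
    paths["summary"].write_text(json.dumps(results.summary_dict(), indent=2))
    return paths


def load_map(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back (t1rho, valid_mask) written by :func:`save_map`."""
    prefix = Path(prefix)
    t1 = load_image(prefix.with_name(prefix.name + "_t1rho.nii"))
    valid = load_image(prefix.with_name(prefix.name + "_valid.nii")) > 0.5
    t1 = np.where(valid, t1, np.nan)
    return t1, valid


def save_rois(roiset: RoiSet, path: str | Path, pixel_spacing_mm: float | None = None) -> Path:
    """Write an ROI set as a NIfTI label volume (0 = background) + JSON sidecar.

    The volume has one label plane per acquisition slice (last axis), so
    ROIs from different slices never collide; the sidecar maps label number
    -> {name, kind, slice_id} and records the slice order.  The exclusion
    mask is written alongside as ``exclusion_<name>``.
    """
    path = Path(path)
    slice_ids = roiset.slice_ids
    shape = roiset.exclusion_mask.shape
    labels = np.zeros((*shape, len(slice_ids)), dtype=np.int16)
    meta: dict[str, dict] = {}
    for i, roi in enumerate(roiset.rois, start=1):
        plane = slice_ids.index(roi.slice_id)
        labels[..., plane][roi.mask] = i
        meta[str(i)] = {"name": roi.label, "kind": roiset.kind, "slice_id": roi.slice_id}
    nib.save(nib.Nifti1Image(labels.astype(np.float64), _affine(pixel_spacing_mm)), path)
    sidecar = {"kind": roiset.kind, "slice_order": slice_ids, "labels": meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    exc_path = path.with_name("exclusion_" + path.name)
    nib.save(
        nib.Nifti1Image(roiset.exclusion_mask.astype(np.float64), _affine(pixel_spacing_mm)),
        exc_path,
    )
    return path


def load_rois(path: str | Path) -> RoiSet:
    path = Path(path)
    labels = load_image(path)
    meta = json.loads(_sidecar_path(path).read_text())
    slice_order = meta.get("slice_order")
    exc_path = path.with_name("exclusion_" + path.name)
    exclusion = load_image(exc_path) > 0.5 if exc_path.exists() else np.zeros(labels.shape[:2], dtype=bool)
    rois = []
    for num, info in sorted(meta["labels"].items(), key=lambda kv: int(kv[0])):
        if labels.ndim == 3 and slice_order:
            plane = labels[..., slice_order.index(info["slice_id"])]
        else:
            plane = labels
        rois.append(
            Roi(label=info["name"], slice_id=info["slice_id"], mask=plane == int(num))
        )
    return RoiSet(rois=tuple(rois), kind=meta["kind"], exclusion_mask=exclusion)


def write_subjects(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read and validate a subjects CSV; errors name columns and line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected columns {SUBJECT_COLUMNS}") from None
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {SUBJECT_COLUMNS}")
    bad_groups = set(df["group"].dropna()) - {CIRRHOSIS, NO_CIRRHOSIS}
    if bad_groups:
        rows = df.index[df["group"].isin(bad_groups)] + 2  # header + 1-based
        raise ValueError(
            f"{path}: invalid group value(s) {sorted(bad_groups)} at line(s) {list(rows)}"
        )
    for col in _NUMERIC_COLUMNS + ["prior_intervention"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value(s) in column {col!r} at line(s) {list(bad + 2)}"
            )
        if coerced.isna().any():
            raise ValueError(
                f"{path}: missing value(s) in column {col!r} at line(s) "
                f"{list(df.index[coerced.isna()] + 2)}"
            )
        df[col] = coerced
    df["prior_intervention"] = df["prior_intervention"].astype(int)
    return df[SUBJECT_COLUMNS]


def _json_safe(value):
    if isinstance(value, float) and not math.isfinite(value):
        return "inf" if value > 0 else ("-inf" if value < 0 else "nan")
    return value


def write_report(reports: list[DiagnosticReport], path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "biomarkers": [
            {k: _json_safe(v) for k, v in dataclasses.asdict(rep).items()} for rep in reports
        ]
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_roc(curves: dict[str, RocCurve], path: str | Path) -> Path:
    """ROC vertex coordinates for all biomarkers as one long-format CSV."""
    path = Path(path)
    frames = []
    for biomarker, c in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "biomarker": biomarker,
                    "threshold": c.thresholds,
                    "fpr": c.fpr,
                    "tpr": c.tpr,
                    "orientation": c.orientation,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config_dict: dict, seed: int) -> Path:
    import hepaquant

    path = Path(path)
    payload = {
        "config_hash": config_hash(config_dict),
        "seed": seed,
        "config": config_dict,
        "versions": {
            "hepaquant": hepaquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
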