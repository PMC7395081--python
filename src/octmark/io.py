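"""Readers and writers for scans, masks, feature volumes and cohort tables.

Three volume dialects are supported:

* **raw**: a headerless little-endian float32 payload (``.raw``) with a
  plain-text key/value sidecar header (``.hdr``). The array is stored in
  C order for axes (x, y, z), i.e. z varies fastest. This dialect
  round-trips bit-for-bit.
* **TIFF**: a multi-page stack, one page per slice (B-scan); each page is
  a (depth, x) image. Geometry and identifiers travel in a JSON
  ImageDescription tag.
* **NIfTI**: ``.nii``/``.nii.gz`` with voxel spacing in the affine.

Cohort metadata travel as CSV with one row per scan.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .errors import CorruptionError, FormatError, ValidationError
from .volume import LESION_CLASSES, OCTVolume, ScanGeometry, SegmentationMaskSet, minmax_normalize

#: Required metadata columns of a cohort table, besides scan_id.
COHORT_COLUMNS = (
    "BCVA",
    "LLVA",
    "RT",
    "IRC",
    "SRF",
    "PED",
    "lesion_area",
    "leakage_area",
)

_LETTER_COLS = ("BCVA", "LLVA")
_NONNEG_COLS = ("RT", "IRC", "SRF", "PED", "lesion_area", "leakage_area")


# ---------------------------------------------------------------------------
# volumes

def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write ``vol`` to ``path``; the dialect is chosen by file extension.

    ``.raw``/``.hdr`` selects the raw dialect, ``.tif``/``.tiff`` a TIFF
    stack and ``.nii``/``.nii.gz`` NIfTI. Returns the path written
    (for the raw dialect: the ``.raw`` file; the sidecar sits next to it).
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        return _write_nifti(vol, path)
    if suffix.endswith((".tif", ".tiff")):
        return _write_tiff(vol, path)
    if suffix.endswith((".raw", ".hdr")) or suffix == "":
        return _write_raw(vol, path)
    raise FormatError(f"unrecognised volume extension: {path.name}")


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume in any supported dialect; intensities are min-max
    normalised to [0, 1] on load."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if suffix.endswith((".tif", ".tiff")):
        return _read_tiff(path)
    if suffix.endswith((".raw", ".hdr")):
        return _read_raw(path)
    raise FormatError(f"unrecognised volume extension: {path.name}")


def _raw_pair(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix.lower() in (".raw", ".hdr") else path
    return stem.with_suffix(".raw"), stem.with_suffix(".hdr")


def _write_raw(vol: OCTVolume, path: Path) -> Path:
    raw_path, hdr_path = _raw_pair(path)
    w, h, d = vol.dims
    header = {
        "dialect": "octmark-raw-v1",
        "width": w,
        "height": h,
        "depth": d,
        "dtype": "float32-le",
        "order": "xyz-c",  # z fastest-varying
        "lateral_extent_mm_x": vol.geometry.lateral_extent_mm[0],
        "lateral_extent_mm_y": vol.geometry.lateral_extent_mm[1],
        "depth_extent_mm": vol.geometry.depth_extent_mm,
        "scan_id": vol.scan_id,
        "patient_id": vol.patient_id,
    }
    hdr_path.write_text("".join(f"{k}: {v}\n" for k, v in header.items()))
    raw_path.write_bytes(np.ascontiguousarray(vol.intensities, dtype="<f4").tobytes())
    return raw_path


def _read_raw(path: Path) -> OCTVolume:
    raw_path, hdr_path = _raw_pair(path)
    if not hdr_path.exists():
        raise FormatError(f"missing sidecar header: {hdr_path}")
    if not raw_path.exists():
        raise FormatError(f"missing raw payload: {raw_path}")
    fields: dict[str, str] = {}
    for line in hdr_path.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip()] = v.strip()
    try:
        dims = (int(fields["width"]), int(fields["height"]), int(fields["depth"]))
    except KeyError as exc:
        raise FormatError(f"sidecar header missing key {exc}") from exc
    geometry = ScanGeometry(
        dims=dims,
        lateral_extent_mm=(
            float(fields.get("lateral_extent_mm_x", 6.0)),
            float(fields.get("lateral_extent_mm_y", 6.0)),
        ),
        depth_extent_mm=float(fields.get("depth_extent_mm", 2.0)),
    )
    payload = np.frombuffer(raw_path.read_bytes(), dtype="<f4")
    expected = dims[0] * dims[1] * dims[2]
    if payload.size != expected:
        raise CorruptionError(
            f"payload holds {payload.size} values but header declares {expected}"
        )
    arr = minmax_normalize(payload.reshape(dims))
    return OCTVolume(
        intensities=arr,
        geometry=geometry,
        scan_id=fields.get("scan_id", ""),
        patient_id=fields.get("patient_id", ""),
    )


def _write_tiff(vol: OCTVolume, path: Path) -> Path:
    # one page per slice (y axis); page layout (depth, x)
    pages = np.transpose(vol.intensities, (1, 2, 0))
    desc = json.dumps(
        {
            "lateral_extent_mm": list(vol.geometry.lateral_extent_mm),
            "depth_extent_mm": vol.geometry.depth_extent_mm,
            "scan_id": vol.scan_id,
            "patient_id": vol.patient_id,
        }
    )
    tifffile.imwrite(path, pages, photometric="minisblack", description=desc)
    return path


def _read_tiff(path: Path) -> OCTVolume:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    arr = np.transpose(pages, (2, 0, 1))  # (x, y, z) back from (y, z, x)
    geometry = ScanGeometry(
        dims=arr.shape,
        lateral_extent_mm=tuple(meta.get("lateral_extent_mm", (6.0, 6.0))),
        depth_extent_mm=float(meta.get("depth_extent_mm", 2.0)),
    )
    return OCTVolume(
        intensities=minmax_normalize(arr),
        geometry=geometry,
        scan_id=meta.get("scan_id", ""),
        patient_id=meta.get("patient_id", ""),
    )


def _write_nifti(vol: OCTVolume, path: Path) -> Path:
    dx, dy, dz = vol.geometry.spacing_um
    affine = np.diag([dx / 1000.0, dy / 1000.0, dz / 1000.0, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.intensities, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    desc = f"scan_id={vol.scan_id};patient_id={vol.patient_id}"
    img.header["descrip"] = desc.encode()[:79]
    nib.save(img, path)
    return path


def _read_nifti(path: Path) -> OCTVolume:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj, dtype=np.float32)
    if arr.ndim != 3:
        raise FormatError(f"NIfTI volume must be 3D, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    w, h, d = arr.shape
    geometry = ScanGeometry(
        dims=arr.shape,
        lateral_extent_mm=(zooms[0] * w, zooms[1] * h),
        depth_extent_mm=zooms[2] * d,
    )
    desc = img.header["descrip"].tobytes().split(b"\x00", 1)[0].decode(errors="replace")
    meta = dict(kv.split("=", 1) for kv in desc.split(";") if "=" in kv)
    return OCTVolume(
        intensities=minmax_normalize(arr),
        geometry=geometry,
        scan_id=meta.get("scan_id", ""),
        patient_id=meta.get("patient_id", ""),
    )


# ---------------------------------------------------------------------------
# masks and feature volumes (npz containers)

def write_masks(maskset: SegmentationMaskSet, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        inner_surface=maskset.inner_surface,
        rpe_surface=maskset.rpe_surface,
        dims=np.asarray(maskset.geometry.dims),
        lateral_extent_mm=np.asarray(maskset.geometry.lateral_extent_mm),
        depth_extent_mm=np.asarray(maskset.geometry.depth_extent_mm),
        scan_id=np.asarray(maskset.scan_id),
        **{f"mask_{cls}": np.packbits(maskset.masks[cls]) for cls in LESION_CLASSES},
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_masks(path: str | Path) -> SegmentationMaskSet:
    with np.load(path, allow_pickle=False) as z:
        dims = tuple(int(v) for v in z["dims"])
        n = dims[0] * dims[1] * dims[2]
        masks = {
            cls: np.unpackbits(z[f"mask_{cls}"], count=n).astype(bool).reshape(dims)
            for cls in LESION_CLASSES
        }
        geometry = ScanGeometry(
            dims=dims,
            lateral_extent_mm=tuple(float(v) for v in z["lateral_extent_mm"]),
            depth_extent_mm=float(z["depth_extent_mm"]),
        )
        return SegmentationMaskSet(
            masks=masks,
            inner_surface=z["inner_surface"],
            rpe_surface=z["rpe_surface"],
            geometry=geometry,
            scan_id=str(z["scan_id"]),
        )


def write_feature_volume(activations: np.ndarray, scan_id: str, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, activations=np.asarray(activations, dtype=np.float32),
                        scan_id=np.asarray(scan_id))
    return path


def read_feature_volume(path: str | Path) -> tuple[np.ndarray, str]:
    with np.load(path, allow_pickle=False) as z:
        return z["activations"], str(z["scan_id"])


# ---------------------------------------------------------------------------
# cohort tables

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cohort table; returns a copy with numeric columns.

    Missing cells stay as NaN (never silently zero). Raises
    :class:`ValidationError` on duplicate scan_ids, out-of-range letter
    scores or negative volumes/areas.
    """
    if "scan_id" not in table.columns:
        raise ValidationError("cohort table must have a scan_id column")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    out = table.copy()
    out["scan_id"] = out["scan_id"].astype(str)
    if out["scan_id"].duplicated().any():
        dupes = out.loc[out["scan_id"].duplicated(), "scan_id"].tolist()
        raise ValidationError(f"duplicate scan_ids: {dupes}")
    for col in COHORT_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in _LETTER_COLS:
        bad = out[col].dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValidationError(f"{col} letter scores must lie in [0, 100]")
    for col in _NONNEG_COLS:
        bad = out[col].dropna()
        if (bad < 0).any():
            raise ValidationError(f"{col} must be non-negative")
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Validate and write a cohort table as CSV."""
    path = Path(path)
    validate_cohort(table).to_csv(path, index=False)
    return path
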