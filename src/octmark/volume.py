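"""Core in-memory containers for OCT scans and their segmentations.

Axis convention (used everywhere in the package): arrays are indexed
``(x, y, z)`` where ``x`` is the fast lateral axis (within a B-scan),
``y`` is the slice axis (across B-scans) and ``z`` is depth. The default
acquisition grid is 512 x 128 x 1024 voxels covering roughly a
6 x 6 mm macular field with 2 mm of depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Exudative lesion classes of neovascular AMD tracked by the package.
LESION_CLASSES = ("IRC", "SRF", "PED", "SHRM")


@dataclass(frozen=True)
class ScanGeometry:
    """Voxel grid dimensions plus the physical field of view.

    Parameters
    ----------
    dims:
        ``(W, H, D)`` voxel counts along (x, y, z).
    lateral_extent_mm:
        En-face field of view, (x extent, y extent) in millimetres.
    depth_extent_mm:
        Axial (z) extent in millimetres.
    """

    dims: tuple[int, int, int] = (512, 128, 1024)
    lateral_extent_mm: tuple[float, float] = (6.0, 6.0)
    depth_extent_mm: float = 2.0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValidationError(f"dims must be three positive integers, got {self.dims!r}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if min(self.lateral_extent_mm) <= 0 or self.depth_extent_mm <= 0:
            raise ValidationError("physical extents must be positive")

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        """Voxel spacing (dx, dy, dz) in micrometres."""
        w, h, d = self.dims
        return (
            self.lateral_extent_mm[0] * 1000.0 / w,
            self.lateral_extent_mm[1] * 1000.0 / h,
            self.depth_extent_mm * 1000.0 / d,
        )

    @property
    def voxel_volume_nl(self) -> float:
        """Volume of one voxel in nanolitres (1 nl = 1e6 um^3)."""
        dx, dy, dz = self.spacing_um
        return dx * dy * dz / 1.0e6

    @property
    def pixel_area_mm2(self) -> float:
        """En-face area of one A-scan position in mm^2."""
        dx, dy, _ = self.spacing_um
        return dx * dy / 1.0e6


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Min-max normalise intensities to [0, 1] as float32.

    A constant array maps to all zeros. The map is idempotent: applying
    it to already-normalised data returns the data unchanged.
    """
    arr = np.asarray(arr, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("volume contains non-finite voxels")
    lo = np.float32(arr.min())
    hi = np.float32(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


@dataclass
class OCTVolume:
    """One 3D OCT scan: normalised intensity grid plus geometry and identifiers."""

    intensities: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    scan_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float32)
        if arr.ndim != 3:
            raise ValidationError(f"intensities must be 3D, got ndim={arr.ndim}")
        if tuple(arr.shape) != tuple(self.geometry.dims):
            raise ValidationError(
                f"intensity shape {arr.shape} does not match geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("volume contains non-finite voxels")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            arr = minmax_normalize(arr)
        self.intensities = arr

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.geometry.dims


@dataclass
class SegmentationMaskSet:
    """Ground-truth lesion masks and retinal layer surfaces for one scan.

    ``masks`` holds one binary (W, H, D) grid per lesion class;
    ``inner_surface`` and ``rpe_surface`` are (W, H) depth maps (in voxel
    units, values in [0, D)) of the inner retinal surface (ILM) and the
    retinal pigment epithelium.
    """

    masks: dict[str, np.ndarray]
    inner_surface: np.ndarray
    rpe_surface: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    scan_id: str = ""

    def __post_init__(self) -> None:
        w, h, d = self.geometry.dims
        for cls in LESION_CLASSES:
            m = np.asarray(self.masks.get(cls, np.zeros((w, h, d), dtype=bool)))
            if m.dtype != bool:
                if not np.isin(m, (0, 1)).all():
                    raise ValidationError(f"mask for {cls} is not binary")
                m = m.astype(bool)
            if m.shape != (w, h, d):
                raise ValidationError(
                    f"mask for {cls} has shape {m.shape}, expected {(w, h, d)}"
                )
            self.masks[cls] = m
        inner = np.asarray(self.inner_surface, dtype=np.float64)
        rpe = np.asarray(self.rpe_surface, dtype=np.float64)
        if inner.shape != (w, h) or rpe.shape != (w, h):
            raise ValidationError("layer surfaces must be (W, H) depth maps")
        if np.any(inner > rpe):
            raise ValidationError("inner surface must lie above (<=) the RPE everywhere")
        if np.any(inner < 0) or np.any(rpe >= d):
            raise ValidationError("layer surfaces must lie within [0, D)")
        self.inner_surface = inner
        self.rpe_surface = rpe
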