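"""Volumetric image container and TIFF z-stack I/O.

An :class:`ImageVolume` holds a 3D grayscale intensity grid indexed
``[x, y, z]`` where X is the nasal-temporal axis, Y the inferior-superior
axis, and Z the anterior-posterior (out-of-plane) axis. Physical position
along each axis is ``index * voxel_size`` in micrometers. On disk a volume
is a multi-page TIFF (one page per z-slice, 16-bit) with a YAML sidecar
carrying acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageVolume", "read_volume", "write_volume"]


@dataclass
class ImageVolume:
    """3D intensity grid with voxel spacing and acquisition metadata.

    Parameters
    ----------
    intensities
        Array of shape ``(nx, ny, nz)``.
    voxel_size
        Spacing per axis in micrometers, ``(dx, dy, dz)``.
    pressure
        Intraocular pressure in mm Hg at acquisition (typically 5, 10 or 45).
    treatment
        ``"buffer"`` or ``"enzyme"``.
    focal_offset
        Recorded focal-depth adjustment in micrometers (signed). When a
        landmark is refocused between acquisitions the offset difference is
        added back to the anterior-posterior displacement.
    specimen, eye
        Free-form identifiers.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.0)
    pressure: float | None = None
    treatment: str | None = None
    focal_offset: float = 0.0
    specimen: str | None = None
    eye: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array (X, Y, Z)")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel spacings must be positive")
        if self.treatment not in (None, "buffer", "enzyme"):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Grid extent per axis in micrometers."""
        return tuple((n - 1) * d for n, d in zip(self.shape, self.voxel_size))

    def with_intensities(self, data: np.ndarray) -> "ImageVolume":
        """Copy of this volume with new intensity data, metadata preserved."""
        return replace(self, intensities=data)


def write_volume(vol: ImageVolume, tiff_path: str | Path, sidecar: dict | None = None) -> None:
    """Write a volume as a multi-page 16-bit TIFF plus a YAML sidecar.

    One TIFF page per z-slice, each page in (Y, X) raster order. The
    sidecar (``<stem>.yaml``) records voxel size and acquisition metadata
    and may carry extra entries (e.g. ground-truth deformation parameters
    for synthetic volumes).
    """
    tiff_path = Path(tiff_path)
    data = np.clip(vol.intensities, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    # pages along Z, rows along Y, columns along X
    tifffile.imwrite(tiff_path, np.transpose(data, (2, 1, 0)))
    doc = {
        "voxel_size_um": list(vol.voxel_size),
        "pressure_mmhg": vol.pressure,
        "treatment": vol.treatment,
        "focal_offset_um": vol.focal_offset,
        "specimen": vol.specimen,
        "eye": vol.eye,
    }
    doc.update(vol.meta)
    if sidecar:
        doc.update(sidecar)
    tiff_path.with_suffix(".yaml").write_text(yaml.safe_dump(doc, sort_keys=False))


def read_volume(tiff_path: str | Path) -> ImageVolume:
    """Read a multi-page TIFF z-stack and its YAML sidecar if present."""
    tiff_path = Path(tiff_path)
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 1, 0)).astype(np.float64)
    meta: dict = {}
    sidecar = tiff_path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    known = {
        "voxel_size_um": tuple(meta.pop("voxel_size_um", (2.5, 2.5, 3.0))),
        "pressure": meta.pop("pressure_mmhg", None),
        "treatment": meta.pop("treatment", None),
        "focal_offset": meta.pop("focal_offset_um", 0.0) or 0.0,
        "specimen": meta.pop("specimen", None),
        "eye": meta.pop("eye", None),
    }
    return ImageVolume(
        intensities=data,
        voxel_size=known["voxel_size_um"],
        pressure=known["pressure"],
        treatment=known["treatment"],
        focal_offset=known["focal_offset"],
        specimen=known["specimen"],
        eye=known["eye"],
        meta=meta,
    )
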