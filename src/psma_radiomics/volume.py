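"""Core image containers: PET volumes and volumes of interest (VOIs).

A :class:`PETVolume` is a 3-D scalar grid with physical voxel spacing in mm,
an origin, a value-unit tag (``"Bq/mL"`` raw activity concentration or
``"SUV"`` standardized uptake value) and the acquisition metadata needed for
SUV scaling (injected dose, body weight).  A :class:`VOI` is a boolean mask on
a volume's grid together with the provenance of the delineation that produced
it (threshold fraction, partial-volume-correction flag, peak and background
uptake).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["PETVolume", "VOI"]

#: recognised value-unit tags
UNITS = ("Bq/mL", "SUV")


@dataclass
class PETVolume:
    """3-D PET image with physical geometry and acquisition metadata.

    Parameters
    ----------
    values
        3-D float array of voxel values, indexed ``(x, y, z)``.
    spacing_mm
        Per-axis voxel spacing in millimetres, all strictly positive.
    origin_mm
        World coordinate of the centre of voxel ``(0, 0, 0)``.
    unit
        ``"Bq/mL"`` for raw activity concentration, ``"SUV"`` after scaling.
    injected_dose_MBq, body_weight_kg
        Acquisition metadata required by SUV scaling; may be ``None`` for
        volumes that are already in SUV units.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "SUV"
    injected_dose_MBq: float | None = None
    body_weight_kg: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "PETVolume":
        """Copy of this volume with new voxel values (geometry/meta preserved)."""
        out = replace(self, values=np.asarray(values, dtype=np.float64))
        if unit is not None:
            out.unit = unit
        return out

    # ------------------------------------------------------------------ NIfTI I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1 with mm spacing in the header affine."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header.set_zooms(self.spacing_mm)
        img.header["descrip"] = self.unit.encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        unit: str | None = None,
        injected_dose_MBq: float | None = None,
        body_weight_kg: float | None = None,
    ) -> "PETVolume":
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        if unit is None:
            descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
            unit = descrip if descrip in UNITS else "SUV"
        return cls(
            values,
            spacing,
            origin,
            unit,
            injected_dose_MBq=injected_dose_MBq,
            body_weight_kg=body_weight_kg,
        )


@dataclass
class VOI:
    """Volume of interest: a boolean mask plus delineation provenance."""

    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    threshold_fraction: float | None = None
    pvc: bool = False
    peak_suv: float | None = None
    background_suv: float | None = None
    label: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def volume_ml(self) -> float:
        """Voxel-count volume in mL."""
        return self.n_voxels * self.voxel_volume_ml

    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of the VOI."""
        return np.argwhere(self.mask)

    def values_in(self, volume: PETVolume | np.ndarray) -> np.ndarray:
        """Voxel values of ``volume`` inside this VOI (flat array)."""
        arr = volume.values if isinstance(volume, PETVolume) else np.asarray(volume)
        if arr.shape != self.mask.shape:
            raise ValueError("volume and VOI grids differ")
        return arr[self.mask]

    # ------------------------------------------------------------------ NIfTI I/O
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, **provenance) -> "VOI":
        img = nib.load(str(path))
        mask = np.asarray(img.dataobj) > 0.5
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(mask, spacing, **provenance)
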