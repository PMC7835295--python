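"""Tumor delineation: background-adapted peak-isocontour region growing.

Tumors are segmented inside a physician-style constraint mask (which keeps
bladder activity out) by growing a 26-connected region from the SUV-peak
position at a threshold

    T = fraction * (SUV_peak - background) + background,

the standard background-corrected relative-threshold family, with the
fraction swept from 50% to 70% in 5% steps.  SUV_peak is the maximum mean
uptake in a 1-mL sphere (EANM convention, ~12.4 mm diameter), and the local
background is estimated from a shell around the constraint mask with a
guard against hot non-target structures such as the bladder.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import PETVolume, VOI

__all__ = [
    "suv_peak",
    "estimate_background",
    "region_grow",
    "delineate_all",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.50, 0.55, 0.60, 0.65, 0.70)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _sphere_kernel(spacing_mm, volume_ml: float = 1.0) -> np.ndarray:
    """Boolean voxel ball approximating a sphere of the given volume."""
    radius_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [max(1, int(np.ceil(radius_mm / s))) for s in spacing_mm]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return sum(g**2 for g in grids) <= radius_mm**2


def sphere_means(volume: PETVolume, volume_ml: float = 1.0) -> np.ndarray:
    """Mean uptake in a sphere centred at every voxel (clipped at grid edges)."""
    kernel = _sphere_kernel(volume.spacing_mm, volume_ml).astype(np.float64)
    num = ndimage.correlate(volume.values, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(
        np.ones_like(volume.values), kernel, mode="constant", cval=0.0
    )
    return num / den


def suv_peak(
    volume: PETVolume, region: np.ndarray, sphere_volume_ml: float = 1.0
) -> tuple[float, tuple[int, int, int]]:
    """SUV_peak: maximum 1-mL-sphere mean over candidate centres in ``region``.

    Returns the peak value and the argmax centre voxel.  Ties are broken by
    the lowest linear voxel index.  If the region is smaller than the peak
    sphere the sphere is clipped to the grid with a warning.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("peak search region is empty")
    voxel_ml = float(np.prod(volume.spacing_mm)) / 1000.0
    if region.sum() * voxel_ml < sphere_volume_ml:
        warnings.warn(
            "region smaller than the peak sphere; sphere clipped to grid",
            stacklevel=2,
        )
    means = sphere_means(volume, sphere_volume_ml)
    masked = np.where(region, means, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence = lowest linear index
    center = np.unravel_index(flat, volume.shape)
    return float(means[center]), tuple(int(c) for c in center)


def estimate_background(
    volume: PETVolume,
    constraint_mask: np.ndarray,
    shell_voxels: int = 2,
    guard_factor: float = 2.5,
) -> float:
    """Local background uptake from a shell around the constraint mask.

    The shell is ``shell_voxels`` morphological dilations (26-connected) of
    the mask minus the mask itself.  Shell voxels hotter than
    ``guard_factor`` times the shell median are discarded, which keeps
    spill-over from adjacent hot structures (bladder) out of the estimate.
    """
    mask = np.asarray(constraint_mask, dtype=bool)
    if not mask.any():
        raise ValueError("constraint mask is empty")
    dilated = ndimage.binary_dilation(mask, structure=_CONN26, iterations=shell_voxels)
    shell = dilated & ~mask
    if not shell.any():
        raise ValueError("background shell is empty (mask fills the grid)")
    shell_vals = volume.values[shell]
    med = float(np.median(shell_vals))
    keep = shell_vals <= guard_factor * max(med, np.finfo(float).tiny)
    if not keep.any():
        keep = np.ones_like(shell_vals, dtype=bool)
    return float(shell_vals[keep].mean())


def region_grow(
    volume: PETVolume,
    constraint_mask: np.ndarray | VOI,
    fraction: float,
    pvc: bool = False,
    label: str = "",
) -> VOI:
    """Grow the tumor VOI at a background-adapted peak-isocontour threshold.

    The VOI is the 26-connected component of ``{SUV >= T}`` (intersected
    with the constraint mask) that contains the SUV-peak centre, with
    ``T = fraction * (peak - background) + background``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1), got {fraction}")
    mask = constraint_mask.mask if isinstance(constraint_mask, VOI) else np.asarray(
        constraint_mask, dtype=bool
    )
    peak, center = suv_peak(volume, mask)
    background = estimate_background(volume, mask)
    threshold = fraction * (peak - background) + background

    candidate = (volume.values >= threshold) & mask
    if not candidate.any():
        raise ValueError(
            f"empty VOI for lesion {label or '<unnamed>'}: threshold {threshold:.3g} "
            "exceeds every voxel in the constraint mask"
        )
    labels, _ = ndimage.label(candidate, structure=_CONN26)
    seed = center if candidate[center] else tuple(
        np.unravel_index(int(np.argmax(np.where(candidate, volume.values, -np.inf))),
                         volume.shape)
    )
    component = labels == labels[seed]
    return VOI(
        component,
        volume.spacing_mm,
        threshold_fraction=fraction,
        pvc=pvc,
        peak_suv=peak,
        background_suv=background,
        label=label,
    )


def delineate_all(
    volume_orig: PETVolume,
    volume_pvc: PETVolume,
    constraint_mask: np.ndarray | VOI,
    fractions=DEFAULT_FRACTIONS,
    label: str = "",
) -> list[VOI]:
    """Delineate at every threshold fraction on original and PVC images.

    Returns ``len(fractions) * 2`` VOIs, each tagged with its threshold
    fraction and PVC provenance (original first, PVC second, fractions in
    the given order).
    """
    if volume_orig.shape != volume_pvc.shape:
        raise ValueError("original and PVC volumes must share the grid")
    vois = []
    for pvc_flag, vol in ((False, volume_orig), (True, volume_pvc)):
        for f in fractions:
            vois.append(region_grow(vol, constraint_mask, f, pvc=pvc_flag, label=label))
    return vois
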