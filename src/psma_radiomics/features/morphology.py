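"""Morphology features of a VOI mask (22 features).

Shape descriptors computed on a triangle mesh of the VOI surface (marching
cubes at the 0.5 iso-level on the binary mask) and on the voxel point
cloud: volumes, surface area and derived compactness measures, principal
axes, and volume/area densities with respect to the axis-aligned bounding
box, approximate enclosing ellipsoid and convex hull.

The centre-of-mass shift uses the intensity-weighted centroid and therefore
needs the image values.  Single-voxel and other mesh-degenerate VOIs fall
back to voxel-based surrogates and are flagged.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["morphology_features", "MORPHOLOGY_FEATURE_NAMES"]

MORPHOLOGY_FEATURE_NAMES = [
    "morph_volume_mesh", "morph_volume_voxel", "morph_surface_area",
    "morph_surface_to_volume_ratio", "morph_compactness_1",
    "morph_compactness_2", "morph_spherical_disproportion",
    "morph_sphericity", "morph_asphericity", "morph_com_shift",
    "morph_max_diameter", "morph_major_axis", "morph_minor_axis",
    "morph_least_axis", "morph_elongation", "morph_flatness",
    "morph_volume_density_aabb", "morph_area_density_aabb",
    "morph_volume_density_aee", "morph_area_density_aee",
    "morph_volume_density_convex_hull", "morph_area_density_convex_hull",
]


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing)  # undo padding offset
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    # Thomsen approximation; relative error below ~1.1%
    p = 1.6075
    term = (a**p * b**p + a**p * c**p + b**p * c**p) / 3.0
    return float(4.0 * np.pi * term ** (1.0 / p))


def morphology_features(
    mask: np.ndarray,
    spacing_mm,
    intensities: np.ndarray | None = None,
    flags: dict | None = None,
) -> dict[str, float]:
    """Compute the 22 morphology features of a connected VOI mask."""
    flags = flags if flags is not None else {}
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=float)
    if not mask.any():
        raise ValueError("VOI is empty")
    n = int(mask.sum())
    voxel_vol = float(np.prod(spacing))
    v_vox = n * voxel_vol

    pts = (np.argwhere(mask) + 0.5) * spacing  # voxel centres, mm

    try:
        verts, faces = _mesh(mask, tuple(spacing))
        area = float(measure.mesh_surface_area(verts, faces))
        v_mesh = _mesh_volume(verts, faces)
        hull_pts = verts
    except (ValueError, RuntimeError):
        flags["morph"] = "degenerate mesh: voxel-based surrogates used"
        # voxel-box surrogates
        v_mesh = v_vox
        area = float(
            2 * (spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2])
            * n ** (2 / 3)
        )
        hull_pts = pts

    v = max(v_mesh, 1e-12)
    sphericity = float((36.0 * np.pi * v**2) ** (1.0 / 3.0) / area)

    # principal axes from the voxel point cloud (population covariance)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / n
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    # centre-of-mass shift (geometric vs intensity-weighted centroid)
    if intensities is not None:
        w = np.clip(np.asarray(intensities, dtype=float)[mask], 0.0, None)
        if w.sum() > 0:
            com_w = (pts * w[:, None]).sum(axis=0) / w.sum()
            com_shift = float(np.linalg.norm(pts.mean(axis=0) - com_w))
        else:
            com_shift = 0.0
    else:
        com_shift = 0.0

    # maximum 3D diameter via convex hull vertices (falls back to all points)
    try:
        hull = ConvexHull(hull_pts)
        hv = hull_pts[hull.vertices]
        v_hull = float(hull.volume)
        a_hull = float(hull.area)
    except (QhullError, ValueError):
        hv = pts
        v_hull, a_hull = v_vox, area
        flags.setdefault("morph", "degenerate hull: voxel surrogates used")
    diffs = hv[:, None, :] - hv[None, :, :]
    max_diam = float(np.sqrt((diffs**2).sum(axis=2)).max())

    # axis-aligned bounding box of the mesh/point cloud
    lo, hi = hull_pts.min(axis=0), hull_pts.max(axis=0)
    aabb_dims = np.maximum(hi - lo, 1e-12)
    v_aabb = float(np.prod(aabb_dims))
    a_aabb = float(
        2 * (aabb_dims[0] * aabb_dims[1] + aabb_dims[0] * aabb_dims[2]
             + aabb_dims[1] * aabb_dims[2])
    )

    # approximate enclosing ellipsoid from the principal semi-axes
    semi = np.maximum(2.0 * np.sqrt(eigvals), 1e-12)
    v_aee = float(4.0 / 3.0 * np.pi * np.prod(semi))
    a_aee = _ellipsoid_area(*semi)

    return {
        "morph_volume_mesh": v_mesh,
        "morph_volume_voxel": v_vox,
        "morph_surface_area": area,
        "morph_surface_to_volume_ratio": area / v,
        "morph_compactness_1": float(v / (np.sqrt(np.pi) * area**1.5)),
        "morph_compactness_2": float(36.0 * np.pi * v**2 / area**3),
        "morph_spherical_disproportion": 1.0 / sphericity,
        "morph_sphericity": sphericity,
        "morph_asphericity": float((area**3 / (36.0 * np.pi * v**2)) ** (1.0 / 3.0) - 1.0),
        "morph_com_shift": com_shift,
        "morph_max_diameter": max_diam,
        "morph_major_axis": major,
        "morph_minor_axis": minor,
        "morph_least_axis": least,
        "morph_elongation": elongation,
        "morph_flatness": flatness,
        "morph_volume_density_aabb": v_mesh / v_aabb,
        "morph_area_density_aabb": area / a_aabb,
        "morph_volume_density_aee": v_mesh / v_aee,
        "morph_area_density_aee": area / a_aee,
        "morph_volume_density_convex_hull": v_mesh / max(v_hull, 1e-12),
        "morph_area_density_convex_hull": area / max(a_hull, 1e-12),
    }
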