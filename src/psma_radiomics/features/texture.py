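"""Texture features on discretized VOIs.

Six matrix families following the Image Biomarker Standardisation
Initiative definitions:

* GLCM  — gray-level co-occurrence (25 features), symmetric, Chebyshev
  distance 1; six aggregations (2D averaged, 2D slice-merged, 2.5D
  direction-merged, 2.5D fully merged, 3D averaged, 3D merged).
* GLRLM — gray-level run lengths (16 features), same six aggregations.
* GLSZM — gray-level size zones (16), three aggregations (2D, 2.5D, 3D).
* GLDZM — gray-level distance zones (16), distance measured in city-block
  steps to the VOI border; three aggregations.
* NGTDM — neighborhood gray-tone difference (5), three aggregations.
* NGLDM — neighboring gray-level dependence (17), coarseness alpha = 0,
  dependence count = 1 + number of equal-level neighbors; three
  aggregations.

Totals 150 + 96 + 48 + 48 + 15 + 51 = 408 features.  Slices are taken
along the third grid axis.  Matrices with no entries (e.g. single-voxel
slices for GLCM) are skipped when per-matrix features are averaged.
Degenerate single-level VOIs yield the defined limits (GLCM joint maximum
1, zero entropies, etc.).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_zones",
    "gldzm_zones",
    "ngtdm_table",
    "ngldm_matrix",
]

# 13 unique 3D direction offsets (half of the 26-neighborhood)
DIRECTIONS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
# 4 unique in-plane directions
DIRECTIONS_2D = [(1, 0), (1, 1), (0, 1), (-1, 1)]

_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _pair_slices(shape, off):
    src, dst = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ======================================================================= GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Symmetric co-occurrence count matrix (Ng x Ng) for one offset."""
    ng = int(levels[mask].max()) if mask.any() else 1
    M = np.zeros((ng, ng))
    src, dst = _pair_slices(levels.shape, offset)
    a, b = levels[src], levels[dst]
    valid = mask[src] & mask[dst]
    a, b = a[valid], b[valid]
    np.add.at(M, (a - 1, b - 1), 1.0)
    return M + M.T


def _glcm_features(M: np.ndarray) -> dict[str, float]:
    n = M.sum()
    ng = M.shape[0]
    if n == 0:
        return {k: 0.0 for k in _GLCM_KEYS}
    P = M / n
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((I * P).sum())
    var = float(((I - mu) ** 2 * P).sum())
    sigma = np.sqrt(var)

    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).ravel() - 2, P.ravel())

    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = float(-_xlog2(p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-_xlog2(p_sum).sum())

    absdiff = np.abs(I - J)
    hxy = float(-_xlog2(P).sum())
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-(P * np.log2(np.where(pxpy > 0, pxpy, 1.0))).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    hx = float(-_xlog2(px).sum())

    if sigma > 0:
        corr = float(((I * J * P).sum() - mu * mu) / (sigma * sigma))
    else:
        corr = 1.0
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = absdiff > 0
    inv_var = float((P[offdiag] / absdiff[offdiag] ** 2).sum()) if offdiag.any() else 0.0

    cm = I + J - 2 * mu
    return {
        "joint_maximum": float(P.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": diff_avg,
        "difference_variance": diff_var,
        "difference_entropy": diff_ent,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "angular_second_moment": float((P**2).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "dissimilarity": float((absdiff * P).sum()),
        "inverse_difference": float((P / (1.0 + absdiff)).sum()),
        "inverse_difference_norm": float((P / (1.0 + absdiff / ng)).sum()),
        "inverse_difference_moment": float((P / (1.0 + absdiff**2)).sum()),
        "inverse_difference_moment_norm": float((P / (1.0 + (absdiff / ng) ** 2)).sum()),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((I * J * P).sum()),
        "cluster_tendency": float((cm**2 * P).sum()),
        "cluster_shade": float((cm**3 * P).sum()),
        "cluster_prominence": float((cm**4 * P).sum()),
        "information_corr_1": ic1,
        "information_corr_2": ic2,
    }


_GLCM_KEYS = list(_glcm_features(np.array([[2.0]])).keys())


# ======================================================================= GLRLM


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, direction
) -> np.ndarray:
    """Run-length count matrix (Ng x Lmax) along one direction.

    Runs are maximal sequences of aligned, equal-level VOI voxels; voxels
    outside the VOI break runs.  Implemented by sorting VOI voxels by
    (line identity, position along line) and splitting at level changes or
    positional gaps.
    """
    if not mask.any():
        return np.zeros((1, 1))
    ng = int(levels[mask].max())
    idx = np.argwhere(mask)
    lv = levels[mask]  # argwhere and boolean indexing share C order
    d = np.asarray(direction)
    dd = int(d @ d)
    t = idx @ d
    line_key = idx * dd - t[:, None] * d
    order = np.lexsort((t,) + tuple(line_key.T[::-1]))
    t_s, lv_s, key_s = t[order], lv[order], line_key[order]

    if len(lv_s) == 1:
        M = np.zeros((ng, 1))
        M[lv_s[0] - 1, 0] = 1
        return M
    same_line = np.all(np.diff(key_s, axis=0) == 0, axis=1)
    contiguous = np.diff(t_s) == dd
    same_run = same_line & contiguous & (np.diff(lv_s) == 0)
    breaks = np.flatnonzero(~same_run)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(lv_s) - 1]))
    lengths = ends - starts + 1
    run_levels = lv_s[starts]
    M = np.zeros((ng, int(lengths.max())))
    np.add.at(M, (run_levels - 1, lengths - 1), 1.0)
    return M


# ============================================================ zone families


def glszm_zones(levels: np.ndarray, mask: np.ndarray, structure) -> list[tuple[int, int]]:
    """(level, zone size) for every connected equal-level zone."""
    zones = []
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == g) & mask, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    return zones


def gldzm_zones(
    levels: np.ndarray, mask: np.ndarray, structure, dist_metric: str
) -> list[tuple[int, int]]:
    """(level, zone distance) pairs; distance = min city-block steps to border.

    Border voxels have distance 1; the array edge counts as VOI border.
    """
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric=dist_metric)
    dist = dist[tuple(slice(1, -1) for _ in mask.shape)]
    zones = []
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == g) & mask, structure=structure)
        if n:
            mins = ndimage.minimum(dist, lab, index=np.arange(1, n + 1))
            zones.extend((int(g), int(m)) for m in np.atleast_1d(mins))
    return zones


def _zones_to_matrix(zones, ng: int) -> np.ndarray:
    if not zones:
        return np.zeros((max(ng, 1), 1))
    jmax = max(j for _, j in zones)
    M = np.zeros((ng, jmax))
    for g, j in zones:
        M[g - 1, j - 1] += 1
    return M


# ============================================== shared run/zone feature forms


def _rlm_features(M: np.ndarray, nv: float) -> dict[str, float]:
    """The 16 emphasis/non-uniformity statistics shared by GLRLM/GLSZM/GLDZM.

    ``j`` is run length, zone size or zone distance depending on family;
    ``nv`` the effective voxel count for the percentage feature.
    """
    ns = M.sum()
    keys = [
        "small_emphasis", "large_emphasis", "low_gl_emphasis", "high_gl_emphasis",
        "small_low_gl_emphasis", "small_high_gl_emphasis",
        "large_low_gl_emphasis", "large_high_gl_emphasis",
        "gl_nonuniformity", "gl_nonuniformity_norm",
        "j_nonuniformity", "j_nonuniformity_norm",
        "percentage", "gl_variance", "j_variance", "j_entropy",
    ]
    if ns == 0:
        return {k: 0.0 for k in keys}
    ng, jmax = M.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, jmax + 1)
    ri = M.sum(axis=1)
    rj = M.sum(axis=0)
    P = M / ns
    pi = ri / ns
    pj = rj / ns
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    I, J = np.meshgrid(i, j, indexing="ij")
    return {
        "small_emphasis": float((rj / j**2).sum() / ns),
        "large_emphasis": float((rj * j**2).sum() / ns),
        "low_gl_emphasis": float((ri / i**2).sum() / ns),
        "high_gl_emphasis": float((ri * i**2).sum() / ns),
        "small_low_gl_emphasis": float((M / (I**2 * J**2)).sum() / ns),
        "small_high_gl_emphasis": float((M * I**2 / J**2).sum() / ns),
        "large_low_gl_emphasis": float((M * J**2 / I**2).sum() / ns),
        "large_high_gl_emphasis": float((M * I**2 * J**2).sum() / ns),
        "gl_nonuniformity": float((ri**2).sum() / ns),
        "gl_nonuniformity_norm": float((ri**2).sum() / ns**2),
        "j_nonuniformity": float((rj**2).sum() / ns),
        "j_nonuniformity_norm": float((rj**2).sum() / ns**2),
        "percentage": float(ns / nv) if nv > 0 else 0.0,
        "gl_variance": float((((I - mu_i) ** 2) * P).sum()),
        "j_variance": float((((J - mu_j) ** 2) * P).sum()),
        "j_entropy": float(-_xlog2(P).sum()),
    }


_GLRLM_RENAME = {
    "small_emphasis": "short_run_emphasis",
    "large_emphasis": "long_run_emphasis",
    "low_gl_emphasis": "low_gl_run_emphasis",
    "high_gl_emphasis": "high_gl_run_emphasis",
    "small_low_gl_emphasis": "short_run_low_gl_emphasis",
    "small_high_gl_emphasis": "short_run_high_gl_emphasis",
    "large_low_gl_emphasis": "long_run_low_gl_emphasis",
    "large_high_gl_emphasis": "long_run_high_gl_emphasis",
    "gl_nonuniformity": "gl_nonuniformity",
    "gl_nonuniformity_norm": "gl_nonuniformity_norm",
    "j_nonuniformity": "run_length_nonuniformity",
    "j_nonuniformity_norm": "run_length_nonuniformity_norm",
    "percentage": "run_percentage",
    "gl_variance": "gl_variance",
    "j_variance": "run_length_variance",
    "j_entropy": "run_entropy",
}
_GLSZM_RENAME = {
    "small_emphasis": "small_zone_emphasis",
    "large_emphasis": "large_zone_emphasis",
    "low_gl_emphasis": "low_gl_zone_emphasis",
    "high_gl_emphasis": "high_gl_zone_emphasis",
    "small_low_gl_emphasis": "small_zone_low_gl_emphasis",
    "small_high_gl_emphasis": "small_zone_high_gl_emphasis",
    "large_low_gl_emphasis": "large_zone_low_gl_emphasis",
    "large_high_gl_emphasis": "large_zone_high_gl_emphasis",
    "gl_nonuniformity": "gl_nonuniformity",
    "gl_nonuniformity_norm": "gl_nonuniformity_norm",
    "j_nonuniformity": "zone_size_nonuniformity",
    "j_nonuniformity_norm": "zone_size_nonuniformity_norm",
    "percentage": "zone_percentage",
    "gl_variance": "gl_variance",
    "j_variance": "zone_size_variance",
    "j_entropy": "zone_size_entropy",
}
_GLDZM_RENAME = {
    "small_emphasis": "small_distance_emphasis",
    "large_emphasis": "large_distance_emphasis",
    "low_gl_emphasis": "low_gl_zone_emphasis",
    "high_gl_emphasis": "high_gl_zone_emphasis",
    "small_low_gl_emphasis": "small_distance_low_gl_emphasis",
    "small_high_gl_emphasis": "small_distance_high_gl_emphasis",
    "large_low_gl_emphasis": "large_distance_low_gl_emphasis",
    "large_high_gl_emphasis": "large_distance_high_gl_emphasis",
    "gl_nonuniformity": "gl_nonuniformity",
    "gl_nonuniformity_norm": "gl_nonuniformity_norm",
    "j_nonuniformity": "zone_distance_nonuniformity",
    "j_nonuniformity_norm": "zone_distance_nonuniformity_norm",
    "percentage": "zone_percentage",
    "gl_variance": "gl_variance",
    "j_variance": "zone_distance_variance",
    "j_entropy": "zone_distance_entropy",
}


# ======================================================================= NGTDM


def _neighbor_offsets(ndim: int):
    ranges = [(-1, 0, 1)] * ndim
    out = []
    for off in np.ndindex(*[3] * ndim):
        o = tuple(v - 1 for v in off)
        if any(o):
            out.append(o)
    return out


def ngtdm_table(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-level occurrence counts n_i and absolute-difference sums s_i.

    For every VOI voxel with at least one VOI neighbor (Chebyshev distance
    1), the difference between its level and the mean level of those
    neighbors is accumulated per gray level.  Returns ``(n, s, nv)`` with
    arrays indexed by level-1 and ``nv`` the number of contributing voxels.
    """
    ng = int(levels[mask].max()) if mask.any() else 1
    nb_sum = np.zeros(levels.shape)
    nb_cnt = np.zeros(levels.shape)
    lv = np.where(mask, levels, 0).astype(float)
    for off in _neighbor_offsets(levels.ndim):
        src, dst = _pair_slices(levels.shape, off)
        nb_sum[src] += lv[dst] * mask[dst]
        nb_cnt[src] += mask[dst]
    valid = mask & (nb_cnt > 0)
    diff = np.zeros(levels.shape)
    diff[valid] = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    n = np.bincount(levels[valid] - 1, minlength=ng).astype(float)
    s = np.bincount(levels[valid] - 1, weights=diff[valid], minlength=ng)
    return n, s, float(valid.sum())


def _ngtdm_features(n: np.ndarray, s: np.ndarray, nv: float) -> dict[str, float]:
    keys = ["coarseness", "contrast", "busyness", "complexity", "strength"]
    if nv == 0:
        return {k: 0.0 for k in keys}
    p = n / nv
    present = p > 0
    i = np.arange(1, len(n) + 1, dtype=float)
    ngp = int(present.sum())
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * (
            float(s.sum()) / nv
        )
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom if denom > 0 else 0.0
        si = s[present]
        num = np.abs(ii - jj) * (pi * si[:, None] + pj * si[None, :]) / (pi + pj)
        complexity = float(num.sum()) / nv
        stot = float(s.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / stot if stot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ======================================================================= NGLDM


def ngldm_matrix(
    levels: np.ndarray, mask: np.ndarray, alpha: int = 0
) -> tuple[np.ndarray, float]:
    """Dependence-count matrix s(i, j): level i, count j = 1 + #dependent neighbors.

    A neighbor (Chebyshev distance 1, inside the VOI) is dependent when its
    level differs from the centre level by at most ``alpha``.
    """
    ng = int(levels[mask].max()) if mask.any() else 1
    dep = np.zeros(levels.shape, dtype=int)
    for off in _neighbor_offsets(levels.ndim):
        src, dst = _pair_slices(levels.shape, off)
        ok = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
        dep[src] += ok
    j = dep[mask] + 1
    lv = levels[mask]
    M = np.zeros((ng, int(j.max())))
    np.add.at(M, (lv - 1, j - 1), 1.0)
    return M, float(mask.sum())


def _ngldm_features(M: np.ndarray, nv: float) -> dict[str, float]:
    base = _rlm_features(M, nv)
    P = M / M.sum() if M.sum() else M
    out = {
        "low_dependence_emphasis": base["small_emphasis"],
        "high_dependence_emphasis": base["large_emphasis"],
        "low_gl_count_emphasis": base["low_gl_emphasis"],
        "high_gl_count_emphasis": base["high_gl_emphasis"],
        "low_dependence_low_gl_emphasis": base["small_low_gl_emphasis"],
        "low_dependence_high_gl_emphasis": base["small_high_gl_emphasis"],
        "high_dependence_low_gl_emphasis": base["large_low_gl_emphasis"],
        "high_dependence_high_gl_emphasis": base["large_high_gl_emphasis"],
        "gl_nonuniformity": base["gl_nonuniformity"],
        "gl_nonuniformity_norm": base["gl_nonuniformity_norm"],
        "dependence_count_nonuniformity": base["j_nonuniformity"],
        "dependence_count_nonuniformity_norm": base["j_nonuniformity_norm"],
        "dependence_count_percentage": base["percentage"],
        "gl_variance": base["gl_variance"],
        "dependence_count_variance": base["j_variance"],
        "dependence_count_entropy": base["j_entropy"],
        "dependence_count_energy": float((P**2).sum()),
    }
    return out


# ================================================================ aggregation


def _mean_over(dicts: list[dict[str, float]], keys) -> dict[str, float]:
    if not dicts:
        return {k: 0.0 for k in keys}
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def _iter_slices(levels, mask):
    for k in range(levels.shape[2]):
        m = mask[:, :, k]
        if m.any():
            yield levels[:, :, k], m


def _pad_matrix(M, shape):
    out = np.zeros(shape)
    out[: M.shape[0], : M.shape[1]] = M
    return out


def _merge(mats):
    if not mats:
        return np.zeros((1, 1))
    shape = (max(m.shape[0] for m in mats), max(m.shape[1] for m in mats))
    return sum(_pad_matrix(m, shape) for m in mats)


def texture_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 408 texture features of a discretized VOI.

    Parameters
    ----------
    levels
        Integer gray levels (1..Ng inside the VOI; values outside the VOI
        are ignored).
    mask
        Boolean VOI mask, same shape.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("VOI is empty")
    ng = int(levels[mask].max())
    out: dict[str, float] = {}

    # ---------------------------------------------------------------- GLCM
    per_sd = []  # (slice index, matrices per direction)
    for k, (lv2, m2) in enumerate(_iter_slices(levels, mask)):
        per_sd.append([glcm_matrix(lv2, m2, d) for d in DIRECTIONS_2D])
    mats_3d = [glcm_matrix(levels, mask, d) for d in DIRECTIONS_3D]

    def glcm_nonzero(mats):
        return [m for m in mats if m.sum() > 0]

    flat_2d = glcm_nonzero([m for row in per_sd for m in row])
    agg = {
        "2d_avg": _mean_over([_glcm_features(m) for m in flat_2d], _GLCM_KEYS),
        "2d_mrg": _mean_over(
            [_glcm_features(_merge(row)) for row in per_sd if _merge(row).sum() > 0],
            _GLCM_KEYS,
        ),
        "25d_avg": _mean_over(
            [
                _glcm_features(_merge([row[d] for row in per_sd]))
                for d in range(len(DIRECTIONS_2D))
                if _merge([row[d] for row in per_sd]).sum() > 0
            ],
            _GLCM_KEYS,
        ),
        "25d_mrg": _glcm_features(_merge([m for row in per_sd for m in row])),
        "3d_avg": _mean_over([_glcm_features(m) for m in glcm_nonzero(mats_3d)], _GLCM_KEYS),
        "3d_mrg": _glcm_features(_merge(mats_3d)),
    }
    for tag, feats in agg.items():
        for k, v in feats.items():
            out[f"glcm_{k}_{tag}"] = v

    # --------------------------------------------------------------- GLRLM
    slice_infos = list(_iter_slices(levels, mask))
    rlm_2d = [
        [(glrlm_matrix(lv2, m2, d), float(m2.sum())) for d in DIRECTIONS_2D]
        for lv2, m2 in slice_infos
    ]
    rlm_3d = [(glrlm_matrix(levels, mask, d), float(mask.sum())) for d in DIRECTIONS_3D]
    keys16 = list(_GLRLM_RENAME)

    def rlm_feats(pairs):
        M = _merge([m for m, _ in pairs])
        nv = sum(n for _, n in pairs)
        return _rlm_features(M, nv)

    rlm_agg = {
        "2d_avg": _mean_over([rlm_feats([p]) for row in rlm_2d for p in row], keys16),
        "2d_mrg": _mean_over([rlm_feats(row) for row in rlm_2d], keys16),
        "25d_avg": _mean_over(
            [rlm_feats([row[d] for row in rlm_2d]) for d in range(len(DIRECTIONS_2D))],
            keys16,
        ),
        "25d_mrg": rlm_feats([p for row in rlm_2d for p in row]),
        "3d_avg": _mean_over([rlm_feats([p]) for p in rlm_3d], keys16),
        "3d_mrg": rlm_feats(rlm_3d),
    }
    for tag, feats in rlm_agg.items():
        for k, v in feats.items():
            out[f"glrlm_{_GLRLM_RENAME[k]}_{tag}"] = v

    # --------------------------------------------------- GLSZM and GLDZM
    def zone_family(zone_fn, rename, prefix):
        per_slice = [zone_fn(lv2, m2, _STRUCT_2D) for lv2, m2 in slice_infos]
        z3 = zone_fn(levels, mask, _STRUCT_3D)
        feats_2d = [
            _rlm_features(_zones_to_matrix(z, ng), float(m2.sum()))
            for z, (_, m2) in zip(per_slice, slice_infos)
        ]
        merged_25d = [z for zs in per_slice for z in zs]
        agg = {
            "2d": _mean_over(feats_2d, keys16),
            "25d": _rlm_features(_zones_to_matrix(merged_25d, ng), float(mask.sum())),
            "3d": _rlm_features(_zones_to_matrix(z3, ng), float(mask.sum())),
        }
        for tag, feats in agg.items():
            for k, v in feats.items():
                out[f"{prefix}_{rename[k]}_{tag}"] = v

    zone_family(lambda l, m, s: glszm_zones(l, m, s), _GLSZM_RENAME, "glszm")
    zone_family(
        lambda l, m, s: gldzm_zones(l, m, s, "taxicab"), _GLDZM_RENAME, "gldzm"
    )

    # --------------------------------------------------------------- NGTDM
    ngtdm_2d = [ngtdm_table(lv2, m2) for lv2, m2 in slice_infos]
    n25 = _merge([n[None, :].T for n, _, _ in ngtdm_2d]).ravel()
    s25 = _merge([s[None, :].T for _, s, _ in ngtdm_2d]).ravel()
    nv25 = sum(nv for _, _, nv in ngtdm_2d)
    n3, s3, nv3 = ngtdm_table(levels, mask)
    ngtdm_agg = {
        "2d": _mean_over(
            [_ngtdm_features(n, s, nv) for n, s, nv in ngtdm_2d if nv > 0],
            ["coarseness", "contrast", "busyness", "complexity", "strength"],
        ),
        "25d": _ngtdm_features(n25, s25, nv25),
        "3d": _ngtdm_features(n3, s3, nv3),
    }
    for tag, feats in ngtdm_agg.items():
        for k, v in feats.items():
            out[f"ngtdm_{k}_{tag}"] = v

    # --------------------------------------------------------------- NGLDM
    ngldm_2d = [ngldm_matrix(lv2, m2) for lv2, m2 in slice_infos]
    keys17 = list(_ngldm_features(np.array([[1.0]]), 1.0).keys())
    ngldm_agg = {
        "2d": _mean_over([_ngldm_features(M, nv) for M, nv in ngldm_2d], keys17),
        "25d": _ngldm_features(
            _merge([M for M, _ in ngldm_2d]), sum(nv for _, nv in ngldm_2d)
        ),
        "3d": _ngldm_features(*ngldm_matrix(levels, mask)),
    }
    for tag, feats in ngldm_agg.items():
        for k, v in feats.items():
            out[f"ngldm_{k}_{tag}"] = v

    return out


def _texture_names() -> list[str]:
    """Deterministic full name list (computed once on a tiny probe VOI)."""
    levels = np.arange(1, 9).reshape(2, 2, 2)
    mask = np.ones((2, 2, 2), dtype=bool)
    return list(texture_features(levels, mask).keys())


TEXTURE_FEATURE_NAMES = _texture_names()
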