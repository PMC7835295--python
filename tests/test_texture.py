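"""Texture matrices against brute-force oracles, plus invariances.

The oracles re-implement every matrix family with naive loops (pair
enumeration, line walking, flood fill, neighbor scans) on small random
VOIs with holes, independently of the vectorised implementation.
"""

import numpy as np
import pytest

from psma_radiomics.features.texture import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    TEXTURE_FEATURE_NAMES,
    _glcm_features,
    _rlm_features,
    glcm_matrix,
    gldzm_zones,
    glrlm_matrix,
    glszm_zones,
    ngldm_matrix,
    ngtdm_table,
    texture_features,
)

from conftest import random_voi


# ----------------------------------------------------------------- oracles


def brute_glcm(levels, mask, off):
    ng = int(levels[mask].max())
    M = np.zeros((ng, ng))
    for idx in np.argwhere(mask):
        j = idx + np.asarray(off)
        if np.all(j >= 0) and np.all(j < np.asarray(levels.shape)):
            if mask[tuple(j)]:
                a, b = levels[tuple(idx)], levels[tuple(j)]
                M[a - 1, b - 1] += 1
                M[b - 1, a - 1] += 1
    return M


def brute_glrlm(levels, mask, d):
    """Walk every maximal run along direction d."""
    d = np.asarray(d)
    shape = np.asarray(levels.shape)
    runs = []
    for idx in np.argwhere(mask):
        prev = idx - d
        if np.all(prev >= 0) and np.all(prev < shape) and mask[tuple(prev)] \
                and levels[tuple(prev)] == levels[tuple(idx)]:
            continue  # not a run start
        length, cur = 0, idx.copy()
        while (np.all(cur >= 0) and np.all(cur < shape) and mask[tuple(cur)]
               and levels[tuple(cur)] == levels[tuple(idx)]):
            length += 1
            cur = cur + d
        runs.append((levels[tuple(idx)], length))
    ng = int(levels[mask].max())
    M = np.zeros((ng, max(l for _, l in runs)))
    for g, l in runs:
        M[g - 1, l - 1] += 1
    return M


def brute_zones(levels, mask, conn_offsets):
    """Flood-fill equal-level zones; returns sorted (level, size) pairs."""
    seen = np.zeros(mask.shape, bool)
    shape = np.asarray(mask.shape)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        g = levels[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for off in conn_offsets:
                u = tuple(np.asarray(v) + off)
                if (np.all(np.asarray(u) >= 0) and np.all(np.asarray(u) < shape)
                        and mask[u] and not seen[u] and levels[u] == g):
                    seen[u] = True
                    stack.append(u)
        zones.append((int(g), size))
    return sorted(zones)


def brute_l1_distance(mask):
    """Exact city-block distance to the VOI border (array edge counts)."""
    shape = np.asarray(mask.shape)
    outside = np.argwhere(~mask)
    dist = np.zeros(mask.shape, int)
    for v in np.argwhere(mask):
        edge = min(min(v[i] + 1, shape[i] - v[i]) for i in range(len(shape)))
        if len(outside):
            d_out = int(np.abs(outside - v).sum(axis=1).min())
            dist[tuple(v)] = min(edge, d_out)
        else:
            dist[tuple(v)] = edge
    return dist


def neighbor_offsets(ndim):
    from itertools import product

    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def brute_ngtdm(levels, mask):
    ng = int(levels[mask].max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    nv = 0
    shape = np.asarray(mask.shape)
    for v in np.argwhere(mask):
        nb = []
        for off in neighbor_offsets(mask.ndim):
            u = v + np.asarray(off)
            if np.all(u >= 0) and np.all(u < shape) and mask[tuple(u)]:
                nb.append(levels[tuple(u)])
        if nb:
            g = levels[tuple(v)]
            n[g - 1] += 1
            s[g - 1] += abs(g - np.mean(nb))
            nv += 1
    return n, s, nv


def brute_ngldm(levels, mask, alpha=0):
    ng = int(levels[mask].max())
    shape = np.asarray(mask.shape)
    entries = []
    for v in np.argwhere(mask):
        dep = 0
        for off in neighbor_offsets(mask.ndim):
            u = v + np.asarray(off)
            if (np.all(u >= 0) and np.all(u < shape) and mask[tuple(u)]
                    and abs(int(levels[tuple(u)]) - int(levels[tuple(v)])) <= alpha):
                dep += 1
        entries.append((levels[tuple(v)], dep + 1))
    M = np.zeros((ng, max(j for _, j in entries)))
    for g, j in entries:
        M[g - 1, j - 1] += 1
    return M


# ------------------------------------------------------------------- tests


def test_glcm_hand_example_horizontal():
    """2x2 slice [[1,1],[2,2]], horizontal pairs: symmetric diagonal 0.5/0.5."""
    levels = np.array([[1, 1], [2, 2]])
    mask = np.ones((2, 2), bool)
    M = glcm_matrix(levels, mask, (0, 1))
    P = M / M.sum()
    assert np.allclose(P, np.diag([0.5, 0.5]))
    feats = _glcm_features(M)
    assert feats["joint_maximum"] == pytest.approx(0.5)
    assert feats["contrast"] == pytest.approx(0.0)
    # direct double-sum check of a second feature
    assert feats["angular_second_moment"] == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(10))
def test_glcm_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    levels, mask = random_voi(rng, shape=(6, 6, 5), n_levels=4)
    for off in DIRECTIONS_3D[:: 3] + [DIRECTIONS_3D[-1]]:
        np.testing.assert_array_equal(glcm_matrix(levels, mask, off),
                                      brute_glcm(levels, mask, off))


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("direction", [(1, 0, 0), (0, 0, 1), (1, 1, 0), (1, -1, 1)])
def test_glrlm_matches_line_walking_oracle(seed, direction):
    rng = np.random.default_rng(100 + seed)
    levels, mask = random_voi(rng, shape=(7, 6, 5), n_levels=3)
    np.testing.assert_array_equal(
        glrlm_matrix(levels, mask, direction), brute_glrlm(levels, mask, direction)
    )


@pytest.mark.parametrize("seed", range(8))
def test_glszm_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    levels, mask = random_voi(rng, shape=(7, 7, 5), n_levels=3)
    got = sorted(glszm_zones(levels, mask, np.ones((3, 3, 3), bool)))
    assert got == brute_zones(levels, mask, neighbor_offsets(3))


@pytest.mark.parametrize("seed", range(6))
def test_gldzm_distances_match_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    levels, mask = random_voi(rng, shape=(6, 6, 6), n_levels=3)
    dist = brute_l1_distance(mask)
    zones = brute_zones(levels, mask, neighbor_offsets(3))
    # brute zone distances: min distance per flood-filled zone
    got = sorted(gldzm_zones(levels, mask, np.ones((3, 3, 3), bool), "taxicab"))
    # oracle: recompute zone minima by re-flooding
    seen = np.zeros(mask.shape, bool)
    expected = []
    shape = np.asarray(mask.shape)
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        g = levels[start]
        stack, dmin = [start], dist[start]
        seen[start] = True
        while stack:
            v = stack.pop()
            dmin = min(dmin, dist[v])
            for off in neighbor_offsets(3):
                u = tuple(np.asarray(v) + off)
                if (np.all(np.asarray(u) >= 0) and np.all(np.asarray(u) < shape)
                        and mask[u] and not seen[u] and levels[u] == g):
                    seen[u] = True
                    stack.append(u)
        expected.append((int(g), int(dmin)))
    assert got == sorted(expected)


@pytest.mark.parametrize("seed", range(8))
def test_ngtdm_matches_neighbor_scan_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    levels, mask = random_voi(rng, shape=(6, 6, 5), n_levels=4)
    n, s, nv = ngtdm_table(levels, mask)
    bn, bs, bnv = brute_ngtdm(levels, mask)
    assert nv == bnv
    np.testing.assert_allclose(n, bn)
    np.testing.assert_allclose(s, bs, atol=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_ngldm_matches_neighbor_count_oracle(seed):
    rng = np.random.default_rng(500 + seed)
    levels, mask = random_voi(rng, shape=(6, 6, 5), n_levels=4)
    M, nv = ngldm_matrix(levels, mask)
    bM = brute_ngldm(levels, mask)
    np.testing.assert_array_equal(M, bM)
    assert nv == mask.sum()


class TestAggregations:
    def test_3d_averaged_equals_per_direction_recomputation(self, rng):
        levels, mask = random_voi(rng, shape=(7, 7, 6), n_levels=5)
        out = texture_features(levels, mask)
        per_dir = [_glcm_features(brute_glcm(levels, mask, d))
                   for d in DIRECTIONS_3D]
        expected = np.mean([f["contrast"] for f in per_dir])
        assert out["glcm_contrast_3d_avg"] == pytest.approx(expected)

    def test_3d_merged_equals_summed_brute_matrices(self, rng):
        levels, mask = random_voi(rng, shape=(7, 6, 6), n_levels=4)
        out = texture_features(levels, mask)
        merged = sum(brute_glcm(levels, mask, d) for d in DIRECTIONS_3D)
        feats = _glcm_features(merged)
        for name in ("joint_entropy", "correlation", "cluster_shade"):
            assert out[f"glcm_{name}_3d_mrg"] == pytest.approx(feats[name])

    def test_25d_merged_runs_pool_slices_and_directions(self, rng):
        levels, mask = random_voi(rng, shape=(6, 6, 4), n_levels=3)
        out = texture_features(levels, mask)
        mats = []
        nv = 0.0
        for k in range(levels.shape[2]):
            m2 = mask[:, :, k]
            if not m2.any():
                continue
            for d in DIRECTIONS_2D:
                mats.append(brute_glrlm(levels[:, :, k], m2, d))
            nv += 4 * m2.sum()
        jmax = max(m.shape[1] for m in mats)
        ng = max(m.shape[0] for m in mats)
        merged = np.zeros((ng, jmax))
        for m in mats:
            merged[: m.shape[0], : m.shape[1]] += m
        expected = _rlm_features(merged, nv)
        assert out["glrlm_run_percentage_25d_mrg"] == pytest.approx(
            expected["percentage"])
        assert out["glrlm_run_entropy_25d_mrg"] == pytest.approx(
            expected["j_entropy"])


class TestDegenerateAndInvariance:
    def test_constant_voi_single_zone_limits(self):
        """A constant VOI is one zone: zone-size non-uniformity 1, GLCM max 1."""
        levels = np.ones((4, 4, 4), dtype=int)
        mask = np.ones((4, 4, 4), bool)
        out = texture_features(levels, mask)
        assert out["glszm_zone_size_nonuniformity_3d"] == pytest.approx(1.0)
        assert out["glcm_joint_maximum_3d_mrg"] == pytest.approx(1.0)
        assert out["glcm_joint_entropy_3d_mrg"] == pytest.approx(0.0)

    def test_all_408_finite_on_random_voi(self, rng):
        levels, mask = random_voi(rng, shape=(10, 10, 10), n_levels=8)
        out = texture_features(levels, mask)
        assert len(out) == 408
        assert list(out.keys()) == TEXTURE_FEATURE_NAMES
        vals = np.array(list(out.values()))
        assert np.all(np.isfinite(vals))

    def test_rotation_invariance_of_3d_merged_features(self, rng):
        """90-degree rotation about the slice axis preserves merged 3D texture."""
        levels, mask = random_voi(rng, shape=(7, 7, 5), n_levels=4)
        lv_rot = np.rot90(levels, axes=(0, 1)).copy()
        m_rot = np.rot90(mask, axes=(0, 1)).copy()
        a = texture_features(levels, mask)
        b = texture_features(lv_rot, m_rot)
        for name in TEXTURE_FEATURE_NAMES:
            if name.endswith("_3d_mrg") or name.endswith("_3d"):
                assert a[name] == pytest.approx(b[name], rel=1e-9), name
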