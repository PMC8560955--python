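"""Texture matrices vs exhaustive brute-force enumeration; feature contracts."""

import itertools

import numpy as np
import pytest

from conftest import random_roi
from lesionsr.radiomics import (
    DIRECTIONS_13,
    FAMILY_COUNTS,
    FEATURE_NAMES,
    extract_features,
    glcm_features,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_features,
    ngtdm_stats,
    quantize,
)
from lesionsr.radiomics.matrices import OFFSETS_26


# ---------------------------------------------------------------------------
# brute-force oracles (independent, loop-based)
# ---------------------------------------------------------------------------

def _in(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def oracle_glcm(levels, direction, ng):
    m = np.zeros((ng, ng), dtype=int)
    for p in np.ndindex(levels.shape):
        for sign in (1, -1):
            q = tuple(c + sign * d for c, d in zip(p, direction))
            if _in(levels.shape, q) and levels[p] > 0 and levels[q] > 0:
                m[levels[p] - 1, levels[q] - 1] += 1
    return m


def oracle_glrlm(levels, direction, ng, lmax):
    m = np.zeros((ng, lmax), dtype=int)
    seen = set()
    for p in np.ndindex(levels.shape):
        prev = tuple(c - d for c, d in zip(p, direction))
        if levels[p] == 0:
            continue
        # start of a run: predecessor outside box, outside mask, or different
        if _in(levels.shape, prev) and levels[prev] == levels[p]:
            continue
        length = 0
        q = p
        while _in(levels.shape, q) and levels[q] == levels[p]:
            length += 1
            q = tuple(c + d for c, d in zip(q, direction))
        key = (p, direction)
        assert key not in seen
        seen.add(key)
        m[levels[p] - 1, length - 1] += 1
    return m


def oracle_glszm(levels, ng):
    zones = []
    visited = np.zeros(levels.shape, dtype=bool)
    for p in np.ndindex(levels.shape):
        if levels[p] == 0 or visited[p]:
            continue
        stack, size, level = [p], 0, levels[p]
        visited[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                q = tuple(c + d for c, d in zip(cur, off))
                if _in(levels.shape, q) and not visited[q] and levels[q] == level:
                    visited[q] = True
                    stack.append(q)
        zones.append((level, size))
    smax = max(s for _, s in zones)
    m = np.zeros((ng, smax), dtype=int)
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def oracle_gldm(levels, ng):
    m = np.zeros((ng, 27), dtype=int)
    for p in np.ndindex(levels.shape):
        if levels[p] == 0:
            continue
        dep = sum(
            1
            for off in OFFSETS_26
            if _in(levels.shape, (q := tuple(c + d for c, d in zip(p, off))))
            and levels[q] == levels[p]
        )
        m[levels[p] - 1, dep] += 1
    return m


def oracle_ngtdm(levels, ng):
    n = np.zeros(ng)
    s = np.zeros(ng)
    n_valid = 0
    for p in np.ndindex(levels.shape):
        if levels[p] == 0:
            continue
        nb = [
            levels[q]
            for off in OFFSETS_26
            if _in(levels.shape, (q := tuple(c + d for c, d in zip(p, off))))
            and levels[q] > 0
        ]
        if not nb:
            continue
        n_valid += 1
        n[levels[p] - 1] += 1
        s[levels[p] - 1] += abs(levels[p] - np.mean(nb))
    return n, s, n_valid


def _crop_levels(q):
    idx = np.argwhere(q.levels > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return q.levels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


class TestQuantize:
    def test_binning_arithmetic_midvalue_upper_bin(self):
        q = quantize(np.array([[[0.0, 0.5, 1.0]]]), np.ones((1, 1, 3), bool), 2)
        np.testing.assert_array_equal(q.levels.ravel(), [1, 2, 2])

    def test_constant_roi_degenerate_flag(self):
        q = quantize(np.full((2, 2, 2), 3.0), np.ones((2, 2, 2), bool), 8)
        assert q.degenerate
        assert np.all(q.levels == 1)

    def test_bijective_on_integer_roi(self):
        vol = np.arange(8, dtype=float).reshape(2, 2, 2)
        q = quantize(vol, np.ones((2, 2, 2), bool), 8)
        np.testing.assert_array_equal(np.sort(q.levels.ravel()), np.arange(1, 9))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), 4)

    def test_levels_zero_outside_mask(self, rng):
        vol, mask = random_roi(rng)
        q = quantize(vol, mask, 4)
        assert np.all(q.levels[~mask] == 0)
        assert np.all((q.levels[mask] >= 1) & (q.levels[mask] <= 4))


@pytest.mark.parametrize("seed", range(50))
def test_matrix_families_match_brute_force(seed):
    """Every matrix family equals exhaustive enumeration on random <=5^3 ROIs."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 6, size=3))
    vol, mask = random_roi(rng, shape=shape, n_levels=int(rng.integers(2, 5)))
    q = quantize(vol, mask, int(rng.integers(2, 5)))
    lv = _crop_levels(q)
    ng = q.max_level

    glcm = glcm_matrices(q)
    for k, d in enumerate(DIRECTIONS_13):
        np.testing.assert_array_equal(glcm[k], oracle_glcm(lv, d, ng))

    glrlm = glrlm_matrices(q)
    for k, d in enumerate(DIRECTIONS_13):
        expected = oracle_glrlm(lv, d, ng, glrlm.shape[2])
        np.testing.assert_array_equal(glrlm[k], expected)

    np.testing.assert_array_equal(glszm_matrix(q), oracle_glszm(lv, ng))
    np.testing.assert_array_equal(gldm_matrix(q), oracle_gldm(lv, ng))

    n_i, p_i, s_i, n_valid = ngtdm_stats(q)
    en, es, env = oracle_ngtdm(lv, ng)
    np.testing.assert_array_equal(n_i, en)
    np.testing.assert_allclose(s_i, es, atol=1e-10)
    assert n_valid == env


class TestHandCases:
    def test_glcm_2x2x1_hand_enumeration(self):
        """Levels [[1,1],[2,2]]: in-plane pair counts enumerated by hand."""
        vol = np.array([[[1.0], [1.0]], [[2.0], [2.0]]])  # shape (2,2,1)
        q = quantize(vol, np.ones((2, 2, 1), bool), 2)
        mats = glcm_matrices(q)
        # direction (0,1,0): pairs within rows of constant level, both orders
        d_idx = DIRECTIONS_13.index((0, 1, 0))
        np.testing.assert_array_equal(mats[d_idx], [[2, 0], [0, 2]])
        # direction (1,0,0): cross-level pairs only
        d_idx = DIRECTIONS_13.index((1, 0, 0))
        np.testing.assert_array_equal(mats[d_idx], [[0, 2], [2, 0]])

    def test_glcm_correlation_matches_pair_oracle(self, rng):
        vol, mask = random_roi(rng, shape=(3, 3, 3))
        q = quantize(vol, mask, 3)
        lv = _crop_levels(q)
        feats = glcm_features(q)
        per_dir = []
        for d in DIRECTIONS_13:
            m = oracle_glcm(lv, d, q.max_level).astype(float)
            p = m / m.sum()
            i = np.arange(1, q.max_level + 1)
            px = p.sum(axis=1)
            mu = (i * px).sum()
            sig = np.sqrt((px * (i - mu) ** 2).sum())
            if sig > 0:
                ii, jj = np.meshgrid(i, i, indexing="ij")
                per_dir.append(((p * ii * jj).sum() - mu**2) / sig**2)
            else:
                per_dir.append(1.0)
        assert feats["GLCM_Correlation"] == pytest.approx(np.mean(per_dir), abs=1e-10)

    def test_constant_roi_sentinels(self):
        q = quantize(np.full((3, 3, 3), 5.0), np.ones((3, 3, 3), bool), 8)
        feats = glcm_features(q)
        assert feats["GLCM_Correlation"] == 1.0
        assert feats["GLCM_DifferenceEntropy"] == 0.0
        assert feats["GLCM_Idn"] == 1.0
        assert feats["GLCM_MCC"] == 1.0

    def test_checkerboard_sum_entropy_closed_form(self):
        """2-level 3D checkerboard: p(x+y) along any axis is concentrated on
        x+y = 3 (all neighbours differ), so SumEntropy = 0 for axis directions
        and the overall mean matches the hand-computed mixture."""
        zz, yy, xx = np.indices((4, 4, 4))
        vol = ((zz + yy + xx) % 2).astype(float)
        q = quantize(vol, np.ones((4, 4, 4), bool), 2)
        mats = glcm_matrices(q)
        entropies = []
        for m in mats:
            p = m / m.sum()
            psum = np.array([p[0, 0], p[0, 1] + p[1, 0], p[1, 1]])  # x+y = 2,3,4
            nz = psum[psum > 0]
            entropies.append(-(nz * np.log2(nz)).sum())
        feats = glcm_features(q)
        assert feats["GLCM_SumEntropy"] == pytest.approx(np.mean(entropies), abs=1e-10)
        # axis-aligned directions alternate strictly: SumEntropy contribution 0
        for axis_dir in [(0, 0, 1), (0, 1, 0), (1, 0, 0)]:
            m = mats[DIRECTIONS_13.index(axis_dir)]
            assert m[0, 0] == m[1, 1] == 0

    def test_glrlm_1x1x4_runs(self):
        vol = np.array([1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 4)
        q = quantize(vol, np.ones((1, 1, 4), bool), 2)
        mats = glrlm_matrices(q)
        run_dir = mats[DIRECTIONS_13.index((0, 0, 1))]
        np.testing.assert_array_equal(run_dir[:, 1], [1, 1])  # two runs of length 2
        assert run_dir.sum() == 2

    def test_constant_line_single_run(self):
        n = 5
        vol = np.stack([np.full((1, n), 1.0), np.full((1, n), 3.0)])
        q = quantize(vol, np.ones((2, 1, n), bool), 2)
        run_dir = glrlm_matrices(q)[DIRECTIONS_13.index((0, 0, 1))]
        # each of the two constant lines is a single run of length n
        assert run_dir[0, n - 1] == 1 and run_dir[1, n - 1] == 1

    def test_glszm_two_disjoint_blobs(self):
        vol = np.zeros((3, 3, 7))
        vol[1, 1, 0:3] = 1.0  # zone of size 3
        mask = np.zeros((3, 3, 7), bool)
        mask[1, 1, 0:3] = True
        mask[1, 1, 5:7] = True
        mask[0, 1, 6] = True
        vol[1, 1, 5:7] = 1.0  # + zone of size 3 (26-connected corner)
        vol[0, 1, 6] = 1.0
        q = quantize(vol + 1.0, mask, 2)  # constant level ROI -> degenerate
        m = glszm_matrix(q)
        assert m[0, 2] == 2  # two zones of size 3 at level 1

    def test_gldm_constant_cube_dependence_counts(self):
        q = quantize(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool), 2)
        m = gldm_matrix(q)
        # 8 corners (7 neighbours), 12 edges (11), 6 faces (17), 1 centre (26)
        assert m[0, 7] == 8 and m[0, 11] == 12 and m[0, 17] == 6 and m[0, 26] == 1
        assert m.sum() == 27

    def test_gldm_single_voxel_dependence_zero(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        q = quantize(np.ones((3, 3, 3)), mask, 2)
        m = gldm_matrix(q)
        assert m[0, 0] == 1 and m.sum() == 1

    def test_ngtdm_constant_all_zero_contrast(self):
        q = quantize(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool), 4)
        feats = ngtdm_features(q)
        assert feats["NGTDM_Contrast"] == 0.0
        _, _, s_i, _ = ngtdm_stats(q)
        np.testing.assert_allclose(s_i, 0.0)

    def test_ngtdm_two_level_block_hand_sums(self):
        """1x1x4 line (1,1,2,2): s_i from hand-computed neighbour means."""
        vol = np.array([1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 4)
        q = quantize(vol, np.ones((1, 1, 4), bool), 2)
        _, _, s_i, n_valid = ngtdm_stats(q)
        # neighbour means: v0:1, v1:(1+2)/2=1.5, v2:(1+2)/2=1.5, v3:2
        assert n_valid == 4
        np.testing.assert_allclose(s_i, [0.5, 0.5])


class TestFeatureVector:
    def test_exactly_75_features_by_family(self, small_phantom):
        vol, mask, _ = small_phantom
        feats = extract_features(vol, mask, 16)
        assert len(feats) == 75
        for family, count in FAMILY_COUNTS.items():
            assert sum(1 for n in feats if n.startswith(family + "_")) == count
        assert sum(FAMILY_COUNTS.values()) == 75

    def test_names_stable_and_deterministic(self, small_phantom):
        vol, mask, _ = small_phantom
        f1 = extract_features(vol, mask, 8)
        f2 = extract_features(vol, mask, 8)
        assert list(f1) == FEATURE_NAMES
        assert f1 == f2

    def test_increasing_affine_transform_invariance(self, rng):
        """Equal-width binning over the ROI's own min-max is invariant under
        any increasing affine rescaling of the intensities."""
        vol, mask = random_roi(rng, shape=(5, 5, 5), n_levels=6)
        vol = vol + 0.1 * rng.random(vol.shape)
        transformed = 3.0 * vol + 2.0
        f1 = extract_features(vol, mask, 4)
        f2 = extract_features(transformed, mask, 4)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-9), name

    def test_axis_permutation_invariance(self, rng):
        vol, mask = random_roi(rng, shape=(4, 5, 6))
        f1 = extract_features(vol, mask, 4)
        for perm in itertools.permutations(range(3)):
            f2 = extract_features(vol.transpose(perm), mask.transpose(perm), 4)
            for name in f1:
                assert f1[name] == pytest.approx(f2[name], abs=1e-9), (name, perm)


class TestConservationLaws:
    def test_matrix_mass_conservation(self, rng):
        vol, mask = random_roi(rng, shape=(4, 4, 4))
        q = quantize(vol, mask, 3)
        lv = _crop_levels(q)
        n_vox = int(mask.sum())

        # GLDM rows partition the ROI voxels
        assert gldm_matrix(q).sum() == n_vox
        # GLSZM zone sizes sum to the ROI voxel count
        m = glszm_matrix(q)
        sizes = np.arange(1, m.shape[1] + 1)
        assert int((m * sizes[None, :]).sum()) == n_vox
        # GLRLM: run lengths weighted by length sum to the voxel count/direction
        for mat in glrlm_matrices(q):
            lengths = np.arange(1, mat.shape[1] + 1)
            assert int((mat * lengths[None, :]).sum()) == n_vox
        # GLCM: each direction counts each ordered in-mask pair twice
        for k, d in enumerate(DIRECTIONS_13):
            a = oracle_glcm(lv, d, q.max_level)
            assert glcm_matrices(q)[k].sum() == a.sum()
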