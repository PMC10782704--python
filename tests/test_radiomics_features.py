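"""Radiomic feature extraction: counts, closed forms, matrix oracles."""

import numpy as np
import pytest

from pctqa import (
    DiscretizationConfig,
    FAMILY_COUNTS,
    compare_features,
    discretize,
    extract_features,
)
from pctqa.radiomics_features import (
    DIRECTIONS_13,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
)

from conftest import make_mask, make_volume


def cube_case(n=6, value=40.0, noise=0.0, seed=0, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    vals = np.full((n, n, n), value) + (rng.normal(0, noise, (n, n, n)) if noise else 0.0)
    return make_volume(vals, spacing=spacing), make_mask(np.ones((n, n, n), bool))


class TestCounts:
    def test_107_features_with_family_split(self, default_case):
        fv = extract_features(default_case.ct, default_case.gtv_masks[0])
        assert len(fv.values) == 107
        for family, n in FAMILY_COUNTS.items():
            assert len(fv.family(family)) == n, family
        assert not any(fv.degenerate.values())

    def test_degenerate_constant_region_flags_texture(self):
        vol, mask = cube_case(4, value=10.0)
        fv = extract_features(vol, mask)
        assert len(fv.values) == 107
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            assert all(fv.degenerate[k] for k in fv.family(family))
        assert not fv.degenerate["firstorder_Mean"]


class TestDiscretize:
    def test_floor_arithmetic(self):
        vals = np.array([0.0, 24.9, 25.0, 50.0]).reshape(4, 1, 1)
        vol = make_volume(vals)
        mask = make_mask(np.ones((4, 1, 1), bool))
        levels, n = discretize(vol, mask, DiscretizationConfig(bin_width=25.0))
        assert levels.ravel().tolist() == [1, 1, 2, 3]
        assert n == 3

    def test_constant_region_single_level(self):
        vol, mask = cube_case(3)
        _, n = discretize(vol, mask)
        assert n == 1

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 30, (4, 4, 4))
        mask = make_mask(np.ones((4, 4, 4), bool))
        l1, _ = discretize(make_volume(vals), mask)
        l2, _ = discretize(make_volume(vals + 123.4), mask)
        np.testing.assert_array_equal(l1, l2)


class TestFirstOrder:
    def test_constant_cube_closed_forms(self):
        vol, mask = cube_case(6, value=40.0)
        fv = extract_features(vol, mask)
        assert fv.values["firstorder_Mean"] == pytest.approx(40.0)
        assert fv.values["firstorder_Variance"] == 0.0
        assert fv.values["firstorder_Energy"] == pytest.approx(216 * 1600.0)
        assert fv.values["firstorder_Entropy"] == pytest.approx(0.0)
        assert fv.values["firstorder_Uniformity"] == pytest.approx(1.0)

    def test_energy_hand_arithmetic(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0]]).reshape(2, 2, 1)
        fv = extract_features(make_volume(vals), make_mask(np.ones((2, 2, 1), bool)))
        assert fv.values["firstorder_Energy"] == pytest.approx(10.0)
        assert fv.values["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt(2.5))

    def test_intensity_stats_independent_of_mask_shape(self):
        # same voxel multiset arranged differently: first-order unchanged
        rng = np.random.default_rng(2)
        vals = rng.normal(40, 10, 64)
        a = extract_features(
            make_volume(vals.reshape(4, 4, 4)), make_mask(np.ones((4, 4, 4), bool))
        )
        b = extract_features(
            make_volume(vals.reshape(8, 8, 1)), make_mask(np.ones((8, 8, 1), bool))
        )
        for k in a.family("firstorder"):
            assert a.values[k] == pytest.approx(b.values[k], rel=1e-12), k


class TestShape:
    def test_cube_closed_forms(self):
        vol, mask = cube_case(8, noise=5.0, seed=3)
        fv = extract_features(vol, mask)
        assert fv.values["shape_VoxelVolume"] == pytest.approx(512.0)
        assert fv.values["shape_MeshVolume"] == pytest.approx(512.0, rel=0.05)
        # marching cubes chamfers the 12 edges, shaving ~8% off the ideal area
        assert fv.values["shape_SurfaceArea"] == pytest.approx(6 * 64.0, rel=0.10)
        # corner chamfering pulls the extreme mesh vertices slightly inward
        assert fv.values["shape_Maximum3DDiameter"] == pytest.approx(8 * np.sqrt(3), rel=0.10)
        assert fv.values["shape_Maximum2DDiameterSlice"] == pytest.approx(
            8 * np.sqrt(2), rel=0.10
        )
        assert fv.values["shape_Elongation"] == pytest.approx(1.0, rel=1e-6)
        assert fv.values["shape_Flatness"] == pytest.approx(1.0, rel=1e-6)

    def test_shape_intensity_invariant(self):
        vol1, mask = cube_case(5, noise=10.0, seed=4)
        vol2, _ = cube_case(5, noise=30.0, seed=5)
        a = extract_features(vol1, mask)
        b = extract_features(vol2, mask)
        for k in a.family("shape"):
            assert a.values[k] == b.values[k], k

    def test_sphere_sphericity_near_one(self, default_case):
        fv = extract_features(default_case.ct, default_case.gtv_masks[0])
        assert 0.85 <= fv.values["shape_Sphericity"] <= 1.0


def brute_force_glcm(levels, mask, n_levels, direction):
    """Nested-loop co-occurrence counts, symmetric."""
    m = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                q = (x + direction[0], y + direction[1], z + direction[2])
                if all(0 <= q[a] < levels.shape[a] for a in range(3)) and mask[q]:
                    i, j = levels[x, y, z] - 1, levels[q] - 1
                    m[i, j] += 1
                    m[j, i] += 1
    return m / m.sum() if m.sum() else m


def brute_force_runs(levels, mask, n_levels, direction):
    """Naive maximal-run counter walking every line voxel by voxel."""
    lv = np.where(mask, levels, 0)
    shape = lv.shape
    runs = {}
    d = np.asarray(direction)
    for start in np.ndindex(shape):
        prev = np.asarray(start) - d
        if all(0 <= prev[a] < shape[a] for a in range(3)):
            continue  # not a line start
        p = np.asarray(start)
        cur_level, cur_len = 0, 0
        while all(0 <= p[a] < shape[a] for a in range(3)):
            v = lv[tuple(p)]
            if v == cur_level:
                cur_len += 1
            else:
                if cur_level > 0:
                    runs[(cur_level, cur_len)] = runs.get((cur_level, cur_len), 0) + 1
                cur_level, cur_len = v, 1
            p = p + d
        if cur_level > 0:
            runs[(cur_level, cur_len)] = runs.get((cur_level, cur_len), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    P = np.zeros((n_levels, max_len))
    for (lev, ln), c in runs.items():
        P[lev - 1, ln - 1] = c
    return P


class TestTextureMatrices:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(7)
        levels = rng.integers(1, 4, (4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.2
        levels = np.where(mask, levels, 0)
        return levels, mask, 3

    def test_glcm_matches_nested_loop_enumeration(self, toy):
        levels, mask, n = toy
        mats = glcm_matrices(levels, mask, n)
        for mat, d in zip(mats, DIRECTIONS_13):
            np.testing.assert_allclose(mat, brute_force_glcm(levels, mask, n, d), atol=1e-12)

    def test_glcm_symmetric(self, toy):
        levels, mask, n = toy
        for mat in glcm_matrices(levels, mask, n):
            np.testing.assert_allclose(mat, mat.T, atol=1e-15)

    def test_glrlm_matches_naive_walker(self, toy):
        levels, mask, n = toy
        for d in DIRECTIONS_13:
            got = glrlm_matrix(levels, mask, n, d)
            want = brute_force_runs(levels, mask, n, d)
            cols = max(got.shape[1], want.shape[1])
            g = np.zeros((n, cols)); g[:, : got.shape[1]] = got
            w = np.zeros((n, cols)); w[:, : want.shape[1]] = want
            np.testing.assert_array_equal(g, w)

    def test_glrlm_total_runs_bounded_by_voxels(self, toy):
        levels, mask, n = toy
        for d in DIRECTIONS_13:
            P = glrlm_matrix(levels, mask, n, d)
            assert P.sum() <= mask.sum()
            # run lengths weighted by counts recover the voxel count
            jv = np.arange(1, P.shape[1] + 1)
            assert (P * jv).sum() == mask.sum()

    def test_glszm_hand_example(self):
        # two zones of level 1 (sizes 2 and 1) and one zone of level 2 (size 3)
        levels = np.zeros((3, 3, 1), dtype=int)
        levels[0, 0, 0] = levels[1, 1, 0] = 1   # touching diagonally: one zone of 2
        levels[2, 1, 0] = 2
        levels[2, 2, 0] = 2
        levels[1, 2, 0] = 2
        mask = levels > 0
        P = glszm_matrix(levels, mask, 2)
        assert P[0, 1] == 1  # level 1, zone size 2 (26-connectivity joins diagonal)
        assert P[1, 2] == 1  # level 2, zone size 3
        assert P.sum() == 2

    def test_ngtdm_hand_example(self):
        # 1-D strip 1,2,1: middle voxel neighbours average (1+1)/2 = 1 -> s=1
        levels = np.array([1, 2, 1]).reshape(3, 1, 1)
        mask = np.ones((3, 1, 1), bool)
        n_i, p_i, s_i, nvp = ngtdm_table(levels, mask, 2)
        assert nvp == 3
        np.testing.assert_allclose(n_i, [2, 1])
        # edge voxels see only the middle (2): |1 - 2| each -> s_1 = 2
        np.testing.assert_allclose(s_i, [2.0, 1.0])

    def test_gldm_hand_example(self):
        # constant pair: each voxel depends on the other -> dependence 2
        levels = np.array([1, 1]).reshape(2, 1, 1)
        mask = np.ones((2, 1, 1), bool)
        P = gldm_matrix(levels, mask, 1, alpha=0)
        assert P[0, 1] == 2  # level 1, dependence 2 (centre + 1 neighbour)
        assert P.sum() == 2  # every voxel contributes exactly once

    def test_gldm_conserves_voxels(self, toy):
        levels, mask, n = toy
        P = gldm_matrix(levels, mask, n)
        assert P.sum() == mask.sum()


class TestCompare:
    def _vectors(self, n_cases, seed=0, shift_feature=None, shift=0.0):
        rng = np.random.default_rng(seed)
        a, b = {}, {}
        for i in range(n_cases):
            vals = rng.normal(40, 12, (6, 6, 6))
            vol = make_volume(vals)
            mask = make_mask(np.ones((6, 6, 6), bool))
            fa = extract_features(vol, mask)
            fb = extract_features(make_volume(vals + rng.normal(0, 0.5, vals.shape)), mask)
            if shift_feature:
                fb.values[shift_feature] = fa.values[shift_feature] + shift
            a[f"c{i}"], b[f"c{i}"] = fa, fb
        return a, b

    def test_identical_sets_nothing_significant(self):
        a, _ = self._vectors(5, seed=1)
        df = compare_features(a, a)
        kept = df[~df["removed"]]
        assert (kept["p_value"] == 1.0).all()
        assert not kept["significant"].any()

    def test_small_organ_degenerates_remove_texture_families(self):
        # 2-voxel "organs": single grey level -> texture families degenerate
        a, b = {}, {}
        for i in range(4):
            vals = np.full((2, 1, 1), 40.0)
            vol = make_volume(vals)
            mask = make_mask(np.ones((2, 1, 1), bool))
            a[f"c{i}"] = extract_features(vol, mask)
            b[f"c{i}"] = extract_features(vol, mask)
        df = compare_features(a, b)
        removed = set(df[df["removed"]]["feature"])
        assert all(f"ngtdm_{n}" in removed for n in ("Coarseness", "Contrast", "Busyness"))
        assert any(f.startswith("glcm_") for f in removed)

    def test_planted_shift_detected(self):
        a, b = self._vectors(8, seed=2, shift_feature="firstorder_Mean", shift=50.0)
        df = compare_features(a, b)
        row = df[df["feature"] == "firstorder_Mean"].iloc[0]
        assert row["p_value"] < 0.05  # exact Wilcoxon, n=8 one-sided shifts

    def test_unmatched_case_sets_rejected(self):
        a, b = self._vectors(3, seed=3)
        del b["c0"]
        with pytest.raises(ValueError, match="case sets"):
            compare_features(a, b)
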