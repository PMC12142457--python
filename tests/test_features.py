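"""Handcrafted geometric features, ranking, SMOTE, and the ML benchmark."""

import numpy as np
import pytest

from brachychoice.errors import ClassMissing, MissingTarget, SmoteError
from brachychoice.features import (
    FEATURE_NAMES,
    BenchmarkModel,
    BenchmarkResults,
    com_offset,
    ctv_volume_cc,
    feature_vector,
    lateral_extension,
    nearest_2cc_distances,
    rank_features,
    smote_oversample,
)
from brachychoice.grid import GridSpec
from brachychoice.structures import StructureRole


@pytest.fixture
def grid32():
    return GridSpec(spacing=(2.0, 2.0, 2.0), shape=(32, 40, 40), origin=(-31.0, -39.0, -39.0))


@pytest.fixture
def vertical_tandem():
    return np.array([[0.0, 0.0, -31.0], [0.0, 0.0, 31.0]])


def _cylinder(grid, radius, center_xy=(0.0, 0.0), z_lo=-20.0, z_hi=20.0):
    yy, xx = np.meshgrid(grid.y_coords, grid.x_coords, indexing="ij")
    disc = (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2
    zsel = (grid.z_coords >= z_lo) & (grid.z_coords <= z_hi)
    return zsel[:, None, None] & disc[None]


class TestVolume:
    def test_voxel_count_times_voxel_volume(self, grid32):
        mask = np.zeros(grid32.shape, dtype=bool)
        mask.ravel()[:250] = True
        assert ctv_volume_cc(mask, grid32) == pytest.approx(2.0)

    def test_rasterized_ellipsoid_close_to_analytic(self, grid32):
        zz, yy, xx = np.meshgrid(grid32.z_coords, grid32.y_coords, grid32.x_coords, indexing="ij")
        mask = (zz / 20) ** 2 + (yy / 15) ** 2 + (xx / 15) ** 2 <= 1.0
        analytic = 4 / 3 * np.pi * 20 * 15 * 15 / 1000.0
        assert ctv_volume_cc(mask, grid32) == pytest.approx(analytic, rel=0.05)

    def test_empty_mask_rejected(self, grid32):
        with pytest.raises(MissingTarget):
            ctv_volume_cc(np.zeros(grid32.shape, dtype=bool), grid32)


class TestLateralExtension:
    def test_coaxial_cylinder(self, grid32, vertical_tandem):
        mask = _cylinder(grid32, 15.0)
        avg, mx = lateral_extension(mask, vertical_tandem, grid32)
        tol = np.sqrt(2) * 2.0  # one in-plane voxel diagonal
        assert avg == pytest.approx(15.0, abs=tol)
        assert mx == pytest.approx(15.0, abs=tol)

    def test_shifted_cylinder_adds_offset(self, grid32, vertical_tandem):
        mask = _cylinder(grid32, 15.0, center_xy=(10.0, 0.0))
        _, mx = lateral_extension(mask, vertical_tandem, grid32)
        assert mx == pytest.approx(25.0, abs=np.sqrt(2) * 2.0)

    def test_matches_per_slice_bruteforce(self, rng, grid32, vertical_tandem):
        mask = rng.random(grid32.shape) > 0.97
        mask[0] = False  # keep at least some empty planes harmless
        avg, mx = lateral_extension(mask, vertical_tandem, grid32)
        per_slice = []
        for zi in range(grid32.shape[0]):
            if not mask[zi].any():
                continue
            yy, xx = np.nonzero(mask[zi])
            d = np.sqrt(grid32.x_coords[xx] ** 2 + grid32.y_coords[yy] ** 2)
            per_slice.append(d.max())
        assert avg == pytest.approx(np.mean(per_slice), abs=1e-9)
        assert mx == pytest.approx(np.max(per_slice), abs=1e-9)

    def test_axis_extended_beyond_tandem_endpoints(self, grid32):
        """CTV slices below the tandem tip use the fitted straight line."""
        short_tandem = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 31.0]])
        mask = _cylinder(grid32, 10.0, z_lo=-20.0, z_hi=-10.0)  # entirely below
        avg, mx = lateral_extension(mask, short_tandem, grid32)
        assert mx == pytest.approx(10.0, abs=np.sqrt(2) * 2.0)


class TestComOffset:
    def test_coaxial_cylinder_is_centered(self, grid32, vertical_tandem):
        avg, mx = com_offset(_cylinder(grid32, 15.0), vertical_tandem, grid32)
        assert avg == pytest.approx(0.0, abs=1.0)
        assert mx == pytest.approx(0.0, abs=1.0)

    def test_shifted_cylinder_reports_shift(self, grid32, vertical_tandem):
        avg, mx = com_offset(
            _cylinder(grid32, 12.0, center_xy=(10.0, 0.0)), vertical_tandem, grid32
        )
        assert avg == pytest.approx(10.0, abs=1.0)
        assert mx == pytest.approx(10.0, abs=1.0)

    def test_matches_handcomputed_centroids(self, rng, grid32, vertical_tandem):
        mask = rng.random(grid32.shape) > 0.98
        avg, mx = com_offset(mask, vertical_tandem, grid32)
        per_slice = []
        for zi in range(grid32.shape[0]):
            if not mask[zi].any():
                continue
            yy, xx = np.nonzero(mask[zi])
            cx = grid32.x_coords[xx].mean()
            cy = grid32.y_coords[yy].mean()
            per_slice.append(np.hypot(cx, cy))
        assert avg == pytest.approx(np.mean(per_slice), abs=1e-9)
        assert mx == pytest.approx(np.max(per_slice), abs=1e-9)


class TestNearest2cc:
    def test_abutting_oar_min_is_grid_spacing(self, grid32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[10:20, 10:20, 10:20] = True
        oar = np.zeros(grid32.shape, dtype=bool)
        oar[10:20, 20:26, 10:20] = True  # shares a face with the CTV
        mx, mn, avg = nearest_2cc_distances(oar, ctv, grid32)
        assert mn == pytest.approx(2.0)
        assert mn <= avg <= mx

    def test_exactly_2cc_oar_uses_all_voxels(self, grid32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[5:10, 5:10, 5:10] = True
        oar = np.zeros(grid32.shape, dtype=bool)
        oar.ravel()[-250:] = True  # exactly 2 cc at 2 mm spacing
        mx, mn, avg = nearest_2cc_distances(oar, ctv, grid32)
        boundary_expected = _bruteforce_2cc(oar, ctv, grid32)
        assert (mx, mn, avg) == pytest.approx(boundary_expected, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        grid = GridSpec(spacing=(2.0, 2.0, 2.0), shape=(20, 20, 20), origin=(-19.0, -19.0, -19.0))
        for _ in range(10):
            ctv = np.zeros(grid.shape, dtype=bool)
            z0, y0, x0 = rng.integers(2, 8, 3)
            ctv[z0 : z0 + 6, y0 : y0 + 6, x0 : x0 + 6] = True
            oar = rng.random(grid.shape) > 0.8
            got = nearest_2cc_distances(oar, ctv, grid)
            expected = _bruteforce_2cc(oar, ctv, grid)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_inside_ctv_counts_as_zero(self, grid32):
        ctv = np.zeros(grid32.shape, dtype=bool)
        ctv[10:20, 10:20, 10:20] = True
        oar = np.zeros(grid32.shape, dtype=bool)
        oar[12:14, 12:14, 12:14] = True
        mx, mn, avg = nearest_2cc_distances(oar, ctv, grid32)
        assert (mx, mn, avg) == (0.0, 0.0, 0.0)


def _bruteforce_2cc(oar, ctv, grid):
    """Independent oracle: all pairwise distances, explicit sort."""
    from scipy import ndimage

    boundary = ctv & ~ndimage.binary_erosion(
        ctv, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    b_idx = np.argwhere(boundary).astype(float) * np.asarray(grid.spacing)
    dists = []
    for voxel in np.argwhere(oar):
        if ctv[tuple(voxel)]:
            dists.append(0.0)
            continue
        p = voxel.astype(float) * np.asarray(grid.spacing)
        dists.append(float(np.sqrt(((b_idx - p) ** 2).sum(axis=1)).min()))
    dists = np.sort(np.asarray(dists), kind="stable")
    n_sel = int(2000.0 // grid.voxel_volume_mm3)
    sel = dists[:n_sel] if len(dists) > n_sel else dists
    return float(sel.max()), float(sel.min()), float(sel.mean())


class TestFeatureVector:
    def _masks(self, grid):
        ctv = np.zeros(grid.shape, dtype=bool)
        ctv[10:22, 14:26, 14:26] = True
        bladder = np.zeros(grid.shape, dtype=bool)
        bladder[10:20, 4:10, 14:26] = True
        return {StructureRole.HR_CTV: ctv, StructureRole.BLADDER: bladder}

    def test_exactly_twenty_entries_in_fixed_order(self, grid32, vertical_tandem):
        fv = feature_vector(self._masks(grid32), vertical_tandem, grid32)
        assert fv.values.shape == (20,)
        assert len(FEATURE_NAMES) == 20
        assert fv["ctv_volume_cc"] > 0
        assert fv["lat_ext_max_mm"] >= fv["lat_ext_avg_mm"]

    def test_missing_oars_take_sentinel(self, grid32, vertical_tandem):
        fv = feature_vector(self._masks(grid32), vertical_tandem, grid32)
        assert fv["rectum_d2cc_max_mm"] == 999.0
        assert fv["sigmoid_d2cc_min_mm"] == 999.0
        assert fv["bladder_d2cc_min_mm"] < 999.0

    def test_mirror_symmetric_phantom_has_no_offset(self, grid32, vertical_tandem):
        masks = {StructureRole.HR_CTV: _cylinder(grid32, 14.0)}
        fv = feature_vector(masks, vertical_tandem, grid32)
        assert fv["com_offset_avg_mm"] == pytest.approx(0.0, abs=1.0)
        assert fv["com_offset_max_mm"] == pytest.approx(0.0, abs=1.0)

    def test_triple_ordering_invariant(self, grid32, vertical_tandem, rng):
        fv = feature_vector(self._masks(grid32), vertical_tandem, grid32)
        s = fv.as_series()
        for role in ("bladder",):
            assert s[f"{role}_d2cc_min_mm"] <= s[f"{role}_d2cc_avg_mm"] <= s[f"{role}_d2cc_max_mm"]

    def test_rotation_about_tandem_axis_invariance(self, grid32, vertical_tandem):
        """90-degree scene rotation leaves extension/offset features fixed."""
        masks = self._masks(grid32)
        fv = feature_vector(masks, vertical_tandem, grid32)
        rot = {k: np.rot90(v, axes=(1, 2)).copy() for k, v in masks.items()}
        fv_rot = feature_vector(rot, vertical_tandem, grid32)
        for name in ("lat_ext_avg_mm", "lat_ext_max_mm", "com_offset_avg_mm", "com_offset_max_mm"):
            assert fv_rot[name] == pytest.approx(fv[name], abs=2.9)  # voxelization


class TestRanking:
    def test_label_copy_ranks_first(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5))
        X[:, 3] = y + rng.normal(0, 0.01, n)
        order, scores = rank_features(X, y)
        assert order[0] == 3

    def test_constant_feature_scores_zero(self, rng):
        y = np.array([0, 1] * 10)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            _, scores = rank_features(X, y)
        assert scores[1] == 0.0

    def test_matches_hand_computed_anova(self):
        """Two classes of three samples each, F computed by hand."""
        X = np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        # between = n*sum((mean_c - mean)^2) = 3*(4+4) = 24 (df 1)
        # within = sum((x - mean_c)^2) = 2 + 2 = 4 (df 4) -> F = 24/1 / (4/4)
        _, scores = rank_features(X, y)
        assert scores[0] == pytest.approx(24.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ClassMissing):
            rank_features(rng.normal(size=(10, 2)), np.ones(10))


class TestSmote:
    def test_balances_counts(self, rng):
        X = rng.normal(size=(140, 4))
        y = np.array([0] * 100 + [1] * 40)
        Xb, yb = smote_oversample(X, y, rng=rng)
        assert (yb == 0).sum() == (yb == 1).sum() == 100
        assert len(Xb) == 200

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 24 + [1] * 6)
        Xb, yb = smote_oversample(X, y, k=3, rng=rng)
        minority = X[y == 1]
        for x_new in Xb[len(X):]:
            # x = a + u (b - a) for some minority pair (a, b): check
            # collinearity and betweenness against all pairs
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    d = b - a
                    denom = np.dot(d, d)
                    u = np.dot(x_new - a, d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(a + u * d, x_new, atol=1e-9):
                        ok = True
            assert ok

    def test_minority_singleton_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(SmoteError):
            smote_oversample(X, y, rng=rng)


class TestBenchmark:
    def test_soft_vote_is_mean_of_model_probabilities(self):
        class Stub:
            classes_ = np.array([0, 1])

            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([1 - np.full(len(X), self.p), np.full(len(X), self.p)])

        model = BenchmarkModel(np.zeros((4, 2)) + np.arange(4)[:, None], np.array([0, 0, 1, 1]), n_top_features=2)
        res = BenchmarkResults(
            model,
            {"svm": Stub(0.9), "rf": Stub(0.8), "knn": Stub(0.2), "dt": Stub(0.4)},
            np.array([0, 1]),
            np.zeros(2),
        )
        probs = res.predict_proba(np.zeros((1, 2)))
        assert probs["soft_vote"].iloc[0] == pytest.approx(0.575)
        assert res.predict(np.zeros((1, 2)))[0] == 1  # 0.575 >= 0.5 -> Syed

    def test_identical_models_vote_like_one(self):
        class Stub:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.tile([0.3, 0.7], (len(X), 1))

        model = BenchmarkModel(np.arange(8).reshape(4, 2), np.array([0, 0, 1, 1]), n_top_features=2)
        res = BenchmarkResults(model, {k: Stub() for k in "abcd"}, np.array([0, 1]), np.zeros(2))
        probs = res.predict_proba(np.zeros((3, 2)))
        assert np.allclose(probs["soft_vote"], 0.7)

    def test_separable_features_reach_high_accuracy(self, rng):
        n = 50
        y = np.array([0] * 30 + [1] * 20)
        X = rng.normal(size=(n, 20))
        X[:, 0] += 6 * y  # one strongly separating feature
        res = BenchmarkModel(X, y, n_top_features=4, seed=0).fit()
        assert res.accuracy(X, y) >= 0.9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ClassMissing):
            BenchmarkModel(rng.normal(size=(10, 20)), np.zeros(10, dtype=int))
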