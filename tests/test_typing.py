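import itertools

import numpy as np
import pytest

from fascicle3d import segmentation as seg
from fascicle3d import typing as typ


def brute_force_two_means(points):
    """Exact 2-means optimum by enumerating all 2-partitions."""
    pts = np.asarray(points, dtype=float)
    best, best_cost = None, np.inf
    n = len(pts)
    for bits in itertools.product([0, 1], repeat=n):
        bits = np.asarray(bits)
        if bits.sum() in (0, n):
            continue
        cost = 0.0
        for side in (0, 1):
            sel = pts[bits == side]
            cost += np.sum((sel - sel.mean(axis=0)) ** 2)
        if cost < best_cost:
            best, best_cost = bits, cost
    return best


def lloyd_kmeans(X, init, max_iter=100):
    """Classical k-means oracle from a given initialization."""
    centers = np.asarray(init, dtype=float).copy()
    for _ in range(max_iter):
        d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)
        new = np.stack([
            X[assign == j].mean(axis=0) if (assign == j).any() else centers[j]
            for j in range(len(centers))
        ])
        if np.max(np.abs(new - centers)) < 1e-6:
            centers = new
            break
        centers = new
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    return centers, np.argmin(d, axis=1)


class TestGradientCurves:
    @pytest.mark.parametrize("r", [5, 8, 11, 15])
    def test_curve_lengths(self, r):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(80, 80, 3)).astype(np.uint8)
        spec = typ.NeighborhoodSpec(r=r)
        curves = typ.directional_gradient_curves(img, (40, 40), spec)
        for d in range(4):
            for k in range(3):
                assert len(curves.first_order[d][k]) == 2 * r
                assert len(curves.second_order[d][k]) == 2 * r - 1

    def test_constant_image_gives_zero_curves(self):
        img = np.full((60, 60, 3), 128, dtype=np.uint8)
        curves = typ.directional_gradient_curves(img, (30, 30), typ.NeighborhoodSpec(11))
        for bank in (curves.first_order, curves.second_order):
            for d in range(4):
                for k in range(3):
                    assert np.all(bank[d][k] == 0)

    def test_alternating_profile_hand_computed(self):
        # row profile 0,255,0,255,... -> first-order +-255, second-order -+510
        img = np.zeros((40, 40), dtype=float)
        img[:, 1::2] = 255.0
        spec = typ.NeighborhoodSpec(r=5)
        curves = typ.directional_gradient_curves(img, (20, 20), spec)
        first = curves.first_order[0][0]  # 0 degrees, single channel
        second = curves.second_order[0][0]
        # profile starts at column 15 (value 255), so differences begin at -255
        expected_first = np.array([-255, 255] * 5)
        assert np.array_equal(first, expected_first)
        assert np.array_equal(second, np.diff(expected_first))
        assert set(np.unique(second)) == {-510, 510}

    def test_border_pixel_rejected(self):
        img = np.zeros((60, 60, 3), dtype=np.uint8)
        with pytest.raises(typ.BorderError):
            typ.directional_gradient_curves(img, (5, 30), typ.NeighborhoodSpec(11))


class TestCurveDescriptors:
    def test_zero_curve(self):
        assert typ.curve_descriptors(np.zeros(10)) == (0.0, 0.0, 0.0)

    def test_hand_enumerated_peaks(self):
        max_amp, second_amp, interval = typ.curve_descriptors([0, 5, 0, 3, 0, 5, 0])
        assert max_amp == 5 and second_amp == 5
        assert interval == 2.0  # peaks at indices 1, 3, 5

    def test_single_peak_interval_zero(self):
        _, _, interval = typ.curve_descriptors([0, 1, 7, 1, 0])
        assert interval == 0.0

    def test_amplitudes_use_magnitude(self):
        max_amp, second_amp, _ = typ.curve_descriptors([0, -9, 0, 4, 0])
        assert max_amp == 9 and second_amp == 4

    def test_plateau_counts_once(self):
        _, _, interval = typ.curve_descriptors([0, 5, 5, 0, 0, 5, 0])
        assert interval == 4.0  # plateau at leftmost index 1, next peak at 5

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            typ.curve_descriptors([1.0])


class TestFeatureMatrix:
    @pytest.mark.parametrize("r", [5, 8, 11, 15])
    def test_feature_dimension_invariant_72(self, r):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(80, 80, 3)).astype(np.uint8)
        vec = typ.feature_vector(img, (40, 40), typ.NeighborhoodSpec(r=r))
        assert vec.shape == (72,)

    def test_matrix_shape_and_determinism(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(100, 100, 3)).astype(np.uint8)
        a, ca = typ.build_feature_matrix(img, 50, typ.NeighborhoodSpec(11), seed=4)
        b, cb = typ.build_feature_matrix(img, 50, typ.NeighborhoodSpec(11), seed=4)
        assert a.shape == (50, 72)
        assert np.array_equal(a, b) and np.array_equal(ca, cb)

    def test_constant_image_zero_amplitude_columns(self):
        img = np.full((100, 100, 3), 77, dtype=np.uint8)
        feats, _ = typ.build_feature_matrix(img, 20, typ.NeighborhoodSpec(11), seed=0)
        assert np.all(feats == 0)

    def test_requesting_too_many_pixels_rejected(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            typ.build_feature_matrix(img, 10**6, typ.NeighborhoodSpec(11), seed=0)

    def test_mask_restricts_sampling(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 255, size=(100, 100, 3)).astype(np.uint8)
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True
        _, coords = typ.build_feature_matrix(img, 30, typ.NeighborhoodSpec(11),
                                             seed=1, mask=mask)
        assert mask[coords[:, 0], coords[:, 1]].all()

    def test_small_r_rejected(self):
        with pytest.raises(ValueError):
            typ.NeighborhoodSpec(r=4)


class TestRoughKMeans:
    def test_eps_zero_equals_classical_kmeans(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(6, 1, (40, 3))])
        init = typ.init_centers(X, 2, seed=7)
        rough = typ.rough_kmeans(X, k=2, eps=0.0, seed=7, init=init)
        centers, assign = lloyd_kmeans(X, init)
        assert np.allclose(rough.centers, centers)
        assert np.array_equal(rough.lower, assign)
        assert all(len(u) == 1 for u in rough.upper)

    def test_six_point_1d_brute_force_optimum(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        res = typ.rough_kmeans(pts, k=2, eps=0.0, seed=0)
        split = brute_force_two_means(pts)
        got = res.lower
        # same partition up to label swap
        same = np.array_equal(got, split) or np.array_equal(got, 1 - split)
        assert same
        assert sorted(np.round(res.centers.ravel(), 6)) == [1.0, 11.0]

    def test_lower_subset_of_upper(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (100, 4))
        res = typ.rough_kmeans(X, k=3, eps=1.3, seed=2)
        for i in range(len(X)):
            if res.lower[i] >= 0:
                assert res.upper[i] == (res.lower[i],)
            else:
                assert len(res.upper[i]) >= 2

    def test_ambiguous_points_exist_for_large_eps(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (200, 2))
        res = typ.rough_kmeans(X, k=3, eps=1.5, seed=1)
        assert (res.lower == -1).any()

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            typ.rough_kmeans(np.zeros((2, 3)), k=3)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            typ.rough_kmeans(np.random.default_rng(0).normal(size=(10, 2)),
                             k=2, w_lower=0.9, w_upper=0.3)

    def test_auto_eps(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (150, 2))
        res = typ.rough_kmeans(X, k=3, eps="auto", seed=3)
        assert 1.0 <= res.eps <= 1.5


@pytest.fixture(scope="module")
def typed_section(flat_stack):
    sections, truth = flat_stack
    img = sections[0].pixels
    fg = seg.preprocess_section(img)
    feats, coords = typ.build_feature_matrix(img, 2500, typ.NeighborhoodSpec(11),
                                             seed=1, mask=fg)
    gt = np.full(len(coords), -1)
    for i, (r, c) in enumerate(coords):
        for fid, m in truth.masks[0].items():
            if m[r, c]:
                gt[i] = {"sensory": 0, "motor": 1, "mixed": 2}[truth.types[fid]]
                break
    return img, truth, feats, coords, gt


class TestTypingEndToEnd:
    def test_pixel_clustering_ari(self, typed_section):
        from sklearn.metrics import adjusted_rand_score

        img, truth, feats, coords, gt = typed_section
        res = typ.rough_kmeans(feats, k=3, seed=0)
        sel = gt >= 0
        ari = adjusted_rand_score(gt[sel], res.hard_assignment()[sel])
        assert ari >= 0.8

    def test_all_fascicles_correctly_typed(self, typed_section):
        img, truth, feats, coords, gt = typed_section
        res = typ.rough_kmeans(feats, k=3, seed=0)
        contours = [truth.contours[0][fid] for fid in truth.masks[0]]
        labels = typ.label_fascicles(contours, res, coords, img)
        expected = [truth.types[fid] for fid in truth.masks[0]]
        assert labels == expected

    def test_accuracy_stable_across_r(self, flat_stack):
        sections, truth = flat_stack
        img = sections[0].pixels
        fg = seg.preprocess_section(img)
        contours = [truth.contours[0][fid] for fid in truth.masks[0]]
        expected = [truth.types[fid] for fid in truth.masks[0]]
        accs = []
        for r in (5, 8, 11, 15):
            feats, coords = typ.build_feature_matrix(
                img, 1500, typ.NeighborhoodSpec(r), seed=1, mask=fg)
            res = typ.rough_kmeans(feats, k=3, seed=0)
            labels = typ.label_fascicles(contours, res, coords, img)
            accs.append(np.mean([a == b for a, b in zip(labels, expected)]))
        assert max(accs) - min(accs) <= 0.05


class TestLabelFascicles:
    def _trivial_clustering(self, lower, centers=3):
        n = len(lower)
        return typ.RoughClustering(
            centers=np.zeros((centers, 72)),
            lower=np.asarray(lower),
            upper=[(int(c),) for c in lower],
            w_lower=0.7, w_upper=0.3, eps=0.0,
        )

    def _gray_image(self):
        # three vertical intensity bands so cluster naming is unambiguous
        img = np.zeros((30, 90, 3), dtype=np.uint8)
        img[:, :30] = 40     # cluster 0 pixels -> darkest -> sensory
        img[:, 30:60] = 220  # cluster 1 pixels -> lightest -> motor
        img[:, 60:] = 130    # cluster 2 pixels -> middle -> mixed
        return img

    def test_unanimous_contour(self):
        img = self._gray_image()
        coords = np.array([[15, c] for c in range(5, 25)])
        clustering = self._trivial_clustering([0] * len(coords))
        square = np.array([[2.0, 2.0], [2.0, 28.0], [28.0, 28.0], [28.0, 2.0]])
        labels = typ.label_fascicles([square], clustering, coords, img)
        assert labels == ["sensory"]

    def test_tie_resolves_to_mixed(self):
        img = self._gray_image()
        coords = np.array([[10, 10], [20, 10], [10, 40], [20, 40]])
        clustering = self._trivial_clustering([0, 0, 1, 1])
        square = np.array([[2.0, 2.0], [2.0, 55.0], [28.0, 55.0], [28.0, 2.0]])
        labels = typ.label_fascicles([square], clustering, coords, img)
        assert labels == ["mixed"]

    def test_contour_without_samples_is_unknown(self):
        img = self._gray_image()
        coords = np.array([[15, 70], [16, 70]])
        clustering = self._trivial_clustering([2, 2])
        far_square = np.array([[2.0, 2.0], [2.0, 20.0], [28.0, 20.0], [28.0, 2.0]])
        labels = typ.label_fascicles([far_square], clustering, coords, img)
        assert labels == ["unknown"]
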