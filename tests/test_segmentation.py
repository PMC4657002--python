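import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fascicle3d import segmentation as seg
from tests.conftest import make_clean_disk, make_granular_disk


def naive_gvf_oracle(edge, mu, n_iter, dt):
    """Literal step-by-step reference implementation of the GVF update."""
    f = np.asarray(edge, dtype=float)
    H, W = f.shape
    fx, fy = np.gradient(f)
    b = fx**2 + fy**2
    u, v = fx.copy(), fy.copy()

    def lap(a, i, j):
        up = a[max(i - 1, 0), j]
        dn = a[min(i + 1, H - 1), j]
        lf = a[i, max(j - 1, 0)]
        rt = a[i, min(j + 1, W - 1)]
        return up + dn + lf + rt - 4.0 * a[i, j]

    for _ in range(n_iter):
        nu, nv = u.copy(), v.copy()
        for i in range(H):
            for j in range(W):
                nu[i, j] = u[i, j] + dt * (mu * lap(u, i, j) - b[i, j] * (u[i, j] - fx[i, j]))
                nv[i, j] = v[i, j] + dt * (mu * lap(v, i, j) - b[i, j] * (v[i, j] - fy[i, j]))
        u, v = nu, nv
    return u, v


class TestPreprocess:
    def test_uniform_image_raises(self):
        with pytest.raises(seg.EmptySectionError):
            seg.preprocess_section(np.full((100, 100, 3), 255, dtype=np.uint8))

    def test_foreground_overlaps_truth(self, small_stack):
        sections, truth = small_stack
        for k in (0, 3):
            fg = seg.preprocess_section(sections[k].pixels)
            tm = np.zeros(fg.shape, bool)
            for m in truth.masks[k].values():
                tm |= m
            jac = (fg & tm).sum() / (fg | tm).sum()
            assert jac >= 0.8

    def test_landmark_dots_excluded(self, small_stack):
        sections, truth = small_stack
        for k in (0, 3):
            fg = seg.preprocess_section(sections[k].pixels)
            assert (fg & truth.landmark_masks[k]).sum() == 0


class TestDynamicClustering:
    def test_single_tight_blob(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([100, 200], 8, size=(500, 2))
        res = seg.cluster_fascicle_pixels(pts)
        assert res.k == 1
        assert np.hypot(*(res.centers[0] - pts.mean(axis=0))) <= 1.0

    def test_two_distant_blobs(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([
            rng.normal([100, 100], 10, size=(400, 2)),
            rng.normal([100, 300], 10, size=(400, 2)),
        ])
        res = seg.cluster_fascicle_pixels(pts)
        assert res.k == 2

    def test_assignment_covers_all_points_and_centers_are_means(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([
            rng.normal([50, 50], 9, size=(300, 2)),
            rng.normal([50, 250], 9, size=(300, 2)),
        ])
        res = seg.cluster_fascicle_pixels(pts)
        assert (res.assignment >= 0).all()
        for j in range(res.k):
            sel = pts[res.assignment == j]
            assert np.allclose(res.centers[j], sel.mean(axis=0))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 300, size=(500, 2))
        a = seg.cluster_fascicle_pixels(pts)
        b = seg.cluster_fascicle_pixels(pts)
        assert a.k == b.k and np.array_equal(a.centers, b.centers)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            seg.cluster_fascicle_pixels(np.empty((0, 2)))

    def test_merge_event_reduces_k_by_one(self):
        from fascicle3d.synthetic_histology import StackConfig, generate_stack

        cfg = StackConfig(n_sections=6, image_size=(480, 640), n_fascicles_initial=2,
                          split_merge_events=[(4, "merge", 0)], rng_seed=2,
                          misalignment_scale=0.0, fascicle_radius_range=(30.0, 38.0))
        sections, truth = generate_stack(cfg)
        ks = {}
        for k in (3, 4):
            fg = seg.preprocess_section(sections[k].pixels)
            ks[k] = seg.cluster_fascicle_pixels(np.argwhere(fg).astype(float)).k
        assert ks[3] == 2 and ks[4] == 1


class TestGVF:
    def test_constant_edge_map_gives_zero_field(self):
        fld = seg.compute_gvf(np.full((20, 20), 0.5), mu=0.2, n_iter=10)
        assert np.allclose(fld.u, 0) and np.allclose(fld.v, 0)

    def test_matches_naive_oracle_on_small_grid(self):
        rng = np.random.default_rng(7)
        edge = rng.random((9, 9))
        mu, n_iter = 0.2, 5
        dt = 1.0 / (4.0 * mu)
        fld = seg.compute_gvf(edge, mu=mu, n_iter=n_iter, dt=dt)
        u_ref, v_ref = naive_gvf_oracle(edge, mu, n_iter, dt)
        assert np.max(np.abs(fld.u - u_ref)) < 1e-12
        assert np.max(np.abs(fld.v - v_ref)) < 1e-12

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            seg.compute_gvf(np.zeros((9, 9)), mu=0.2, n_iter=1, dt=10.0)

    def test_capture_range_points_toward_disk(self, granular_disk):
        img, (cr, cc), radius = granular_disk
        fld = seg.compute_gvf(seg.edge_map(img), mu=0.2, n_iter=80)
        probe = np.array([[cr, cc + radius + 10.0]])
        F = fld.sample(probe)[0]
        toward = np.array([0.0, -1.0])  # boundary direction from the probe
        assert F @ toward > 0

    def test_field_magnitude_bounded(self, granular_disk):
        img, _, _ = granular_disk
        em = seg.edge_map(img)
        fld = seg.compute_gvf(em, mu=0.2, n_iter=80)
        fx, fy = np.gradient(em)
        bound = np.max(np.hypot(fx, fy))
        assert np.max(np.hypot(fld.u, fld.v)) <= bound + 1e-9


class TestSnake:
    def test_fixed_point_with_zero_forces(self):
        zero = seg.GVFField(u=np.zeros((100, 100)), v=np.zeros((100, 100)),
                            mu=0.2, iterations_run=0)
        init = seg.circle_contour((50, 50), 20, n=60)
        p = seg.SnakeParams(alpha=0.0, beta=0.0, n_vertices=60, max_iter=50)
        out = seg.evolve_snake(init, zero, p)
        assert out.converged and out.iterations == 1
        assert np.allclose(out.vertices, seg._resample_closed(init.vertices, 60))

    def test_granular_disk_both_modes(self, granular_disk):
        img, (cr, cc), radius = granular_disk
        fld = seg.compute_gvf(seg.edge_map(img), mu=0.2, n_iter=80)
        finals = {}
        iters = {}
        for mode in ("classical", "improved"):
            init = seg.circle_contour((cr, cc), 72, n=100)
            out = seg.evolve_snake(init, fld, seg.SnakeParams(mode=mode, max_iter=400))
            radii = np.hypot(out.vertices[:, 0] - cr, out.vertices[:, 1] - cc)
            assert np.mean(np.abs(radii - radius)) <= 2.0
            finals[mode] = out.vertices
            iters[mode] = out.iterations
        D = cdist(finals["classical"], finals["improved"])
        hausdorff = max(D.min(axis=0).max(), D.min(axis=1).max())
        assert hausdorff <= 1.0
        assert iters["improved"] <= iters["classical"]

    def test_collapse_raises(self):
        zero = seg.GVFField(u=np.zeros((100, 100)), v=np.zeros((100, 100)),
                            mu=0.2, iterations_run=0)
        init = seg.circle_contour((50, 50), 10, n=40)
        p = seg.SnakeParams(alpha=2.0, beta=0.0, n_vertices=40, step=2.0,
                            max_iter=500, tol=0.0)
        with pytest.raises(seg.CollapseError):
            seg.evolve_snake(init, zero, p)

    def test_energy_monotone_on_clean_disk(self, clean_disk):
        img, (cr, cc), radius = clean_disk
        em = seg.edge_map(img)
        fld = seg.compute_gvf(em, mu=0.2, n_iter=80)
        p = seg.SnakeParams(mode="improved", max_iter=1)
        contour = seg.circle_contour((cr, cc), 72, n=100)
        prev = seg.snake_energy(seg._resample_closed(contour.vertices, 100), em,
                                p.alpha, p.beta)
        for _ in range(60):
            contour = seg.evolve_snake(contour, fld, p)
            e = seg.snake_energy(contour.vertices, em, p.alpha, p.beta)
            assert e <= prev + 1e-6
            prev = e

    def test_improved_mode_tangent_force_negligible(self, clean_disk):
        img, (cr, cc), radius = clean_disk
        fld = seg.compute_gvf(seg.edge_map(img), mu=0.2, n_iter=80)
        init = seg.circle_contour((cr, cc), 72, n=100)
        out = seg.evolve_snake(init, fld, seg.SnakeParams(mode="improved", max_iter=400))
        assert out.converged
        normal_mag, tangent_mag = seg.force_decomposition(out.vertices, fld)
        assert tangent_mag <= 0.05 * normal_mag

    def test_invalid_mode_rejected(self):
        zero = seg.GVFField(u=np.zeros((10, 10)), v=np.zeros((10, 10)),
                            mu=0.2, iterations_run=0)
        with pytest.raises(ValueError):
            seg.evolve_snake(seg.circle_contour((5, 5), 2), zero,
                             seg.SnakeParams(mode="banana"))


class TestExtractContours:
    def test_one_contour_per_cluster(self, small_stack):
        sections, truth = small_stack
        fg = seg.preprocess_section(sections[0].pixels)
        clusters = seg.cluster_fascicle_pixels(np.argwhere(fg).astype(float))
        res = seg.extract_fascicle_contours(sections[0].pixels, clusters)
        assert len(res.contours) + len(res.failed_clusters) == clusters.k

    def test_contours_near_truth(self, small_stack):
        sections, truth = small_stack
        fg = seg.preprocess_section(sections[0].pixels)
        clusters = seg.cluster_fascicle_pixels(np.argwhere(fg).astype(float))
        res = seg.extract_fascicle_contours(sections[0].pixels, clusters)
        assert len(res.contours) == truth.fascicle_count(0)
        geo = truth.fascicle_geometry[0]
        for contour in res.contours:
            center = contour.vertices.mean(axis=0)
            fid = min(geo, key=lambda f: np.hypot(geo[f][0] - center[0],
                                                  geo[f][1] - center[1]))
            cr, cc, radius = geo[fid]
            t = truth.transforms[0]
            c_sec = t.inverse_map(np.array([cr, cc]))
            radii = np.hypot(contour.vertices[:, 0] - c_sec[0],
                             contour.vertices[:, 1] - c_sec[1])
            assert np.mean(np.abs(radii - radius)) <= 2.0

    def test_near_touching_fascicles_stay_disjoint(self):
        import shapely.geometry as sgeom

        # two granular disks, radius 40, centers 92 px apart -> 12 px gap
        img1, _, _ = make_granular_disk(radius=40, size=220, seed=1)
        img = np.full((220, 360), 236.0)
        img[:, :180] = np.minimum(img[:, :180], img1[:, 20:200])
        img2, _, _ = make_granular_disk(radius=40, size=220, seed=2)
        img[:, 92:272] = np.minimum(img[:, 92:272], img2[:, 20:200])
        fg = seg.preprocess_section(np.stack([img] * 3, axis=-1).astype(np.uint8))
        clusters = seg.cluster_fascicle_pixels(np.argwhere(fg).astype(float))
        assert clusters.k == 2
        res = seg.extract_fascicle_contours(np.stack([img] * 3, axis=-1).astype(np.uint8),
                                            clusters)
        polys = [sgeom.Polygon(c.vertices) for c in res.contours]
        assert all(p.is_simple for p in polys)
        inter = polys[0].intersection(polys[1]).area
        assert inter <= 0.02 * min(p.area for p in polys)

    def test_contours_are_simple_polygons(self, small_stack):
        import shapely.geometry as sgeom

        sections, _ = small_stack
        fg = seg.preprocess_section(sections[1].pixels)
        clusters = seg.cluster_fascicle_pixels(np.argwhere(fg).astype(float))
        res = seg.extract_fascicle_contours(sections[1].pixels, clusters)
        for c in res.contours:
            assert len(c.vertices) >= 8
            assert sgeom.Polygon(c.vertices).is_simple
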