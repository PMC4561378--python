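import numpy as np
import pytest
from skimage.morphology import convex_hull_image
from skimage.transform import rotate

from mamseg.errors import ParameterError
from mamseg.shapedesc import (
    CentroidDistanceFunction,
    boundary_moments,
    centroid_distance,
    convexity,
    describe,
    fourier_descriptors,
    rectangularity,
)


def cdf_from_r(r):
    r = np.asarray(r, dtype=float)
    return CentroidDistanceFunction(r=r, centroid=np.zeros(2),
                                    boundary=np.zeros((len(r), 2)))


def polar_mask(shape, center, radius_fn, n=1440):
    from skimage.draw import polygon as draw_polygon
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = radius_fn(th)
    x = center[0] + rr * np.cos(th)
    y = center[1] + rr * np.sin(th)
    mask = np.zeros(shape, dtype=bool)
    pr, pc = draw_polygon(y, x, shape=shape)
    mask[pr, pc] = True
    return mask


class TestCentroidDistance:
    def test_disk_radius_recovered(self):
        yy, xx = np.mgrid[0:96, 0:96]
        mask = np.hypot(xx - 48, yy - 48) <= 30
        cdf = centroid_distance(mask)
        assert np.all(np.abs(cdf.r - 30) <= 0.6)

    def test_square_min_max(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:40, 20:40] = True  # side 20
        cdf = centroid_distance(mask)
        assert cdf.r.min() == pytest.approx(10, abs=0.6)
        assert cdf.r.max() == pytest.approx(10 * np.sqrt(2), abs=0.6)

    def test_translation_invariance(self):
        yy, xx = np.mgrid[0:96, 0:96]
        mask = np.hypot(xx - 40, yy - 45) <= 22
        shifted = np.roll(np.roll(mask, 7, axis=1), -3, axis=0)
        a = centroid_distance(mask).r
        b = centroid_distance(shifted).r
        assert np.allclose(a, b, atol=1e-6)

    def test_border_touching_warns(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[0:20, 10:30] = True
        with pytest.warns(UserWarning, match="border"):
            centroid_distance(mask)


class TestBoundaryMoments:
    def test_constant_r_gives_zero(self):
        f1, f2, f3 = boundary_moments(cdf_from_r(np.full(256, 12.0)))
        assert f1 == 0 and f2 == 0 and f3 == 0

    def test_hand_worked_two_sample(self):
        """r=[1,3]: m1=2, mu2=1, mu4=1 -> F1=F2=0.5, F3=0."""
        f1, f2, f3 = boundary_moments(cdf_from_r([1.0, 3.0]))
        assert f1 == pytest.approx(0.5)
        assert f2 == pytest.approx(0.5)
        assert f3 == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [0.5, 2.0, 17.3])
    def test_scale_invariance_exact(self, k):
        rng = np.random.default_rng(1)
        r = rng.uniform(10, 20, 256)
        a = boundary_moments(cdf_from_r(r))
        b = boundary_moments(cdf_from_r(k * r))
        assert a == pytest.approx(b, rel=1e-12)


class TestFourierDescriptors:
    def test_constant_r_all_zero(self):
        fd = fourier_descriptors(cdf_from_r(np.full(512, 9.0)))
        assert np.all(fd == 0)

    def test_single_harmonic_closed_form(self):
        """r(n) = 10 + 2 cos(2 pi 3 n / N): |a_3| = 1, |a_0| = 10."""
        n = np.arange(512)
        fd = fourier_descriptors(cdf_from_r(10 + 2 * np.cos(2 * np.pi * 3 * n / 512)))
        assert fd[2] == pytest.approx(0.1, abs=1e-6)
        assert np.delete(fd, 2).max() < 1e-6

    def test_start_point_shift_invariance(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(10, 20, 512)
        a = fourier_descriptors(cdf_from_r(r))
        b = fourier_descriptors(cdf_from_r(np.roll(r, 137)))
        assert np.allclose(a, b, atol=1e-12)

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(5, 15, 512)
        a = np.fft.fft(r) / len(r)
        assert np.sum(np.abs(a) ** 2) == pytest.approx(np.mean(r**2), abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            fourier_descriptors(cdf_from_r(np.full(100, 5.0)), k=60)


class TestConvexity:
    def test_disk_convex(self, disk_mask):
        assert convexity(disk_mask) >= 0.99

    def test_plus_sign_matches_bruteforce_hull(self):
        """Exhaustive oracle: gift-wrap the foreground pixel centers and
        count pixels inside every hull half-plane."""
        from scipy.spatial import Delaunay
        plus = np.zeros((80, 80), dtype=bool)
        plus[35:45, 10:70] = True
        plus[10:70, 35:45] = True
        pts = np.argwhere(plus)
        yy, xx = np.mgrid[0:80, 0:80]
        # membership oracle: pixel center lies in some simplex of the
        # triangulated foreground point set <=> inside its convex hull
        inside = Delaunay(pts).find_simplex(
            np.column_stack([yy.ravel(), xx.ravel()])) >= 0
        got = convexity(plus, area_mode="pixel")
        assert got == pytest.approx(plus.sum() / inside.sum(), abs=1e-9)

    def test_notch_decreases_convexity(self, disk_mask):
        notched = disk_mask.copy()
        notched[58:70, 64:105] = False  # deep wedge into the disk
        assert convexity(notched) < convexity(disk_mask)


class TestRectangularity:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((80, 100), dtype=bool)
        mask[20:40, 20:60] = True  # 20 x 40
        assert rectangularity(mask) >= 0.99

    def test_disk_pi_over_four(self, disk_mask):
        assert rectangularity(disk_mask) == pytest.approx(np.pi / 4, abs=0.01)

    def test_rotated_rectangle_matches_exhaustive_search(self):
        """Minimum rotated rectangle equals an exhaustive 0.1-degree scan
        of bounding-box areas over the boundary polygon."""
        from mamseg.shapedesc import boundary_polygon
        mask = np.zeros((80, 100), dtype=bool)
        mask[20:40, 20:60] = True
        rot = rotate(mask.astype(float), 30, resize=True, order=0) > 0.5
        poly = boundary_polygon(rot)
        best = np.inf
        for deg in np.arange(0, 90, 0.1):
            t = np.radians(deg)
            c, s = np.cos(t), np.sin(t)
            u = poly @ np.array([c, -s])
            v = poly @ np.array([s, c])
            best = min(best, np.ptp(u) * np.ptp(v))
        from shapely.geometry import Polygon
        from shapely import minimum_rotated_rectangle
        area_pkg = minimum_rotated_rectangle(Polygon(poly)).area
        assert area_pkg == pytest.approx(best, rel=0.005)


class TestDescribe:
    def test_disk_bundle(self, disk_mask):
        d = describe(disk_mask)
        assert d.f1 == pytest.approx(0, abs=0.02)
        assert d.f3 == abs(d.f1 - d.f2)
        assert np.all(d.fd <= 0.01)
        assert d.sc >= 0.99
        assert d.sr == pytest.approx(np.pi / 4, abs=0.01)
        assert d.area == disk_mask.sum()

    def test_deterministic(self, disk_mask):
        a, b = describe(disk_mask), describe(disk_mask)
        assert a.f1 == b.f1 and np.array_equal(a.fd, b.fd) and a.sr == b.sr

    def test_spiculated_rougher_than_hull(self):
        spic = polar_mask((160, 160), (80, 80),
                          lambda th: 40 * (1 + 0.25 * np.cos(8 * th)))
        hull = convex_hull_image(spic)
        ds, dh = describe(spic), describe(hull)
        assert ds.f1 > dh.f1
        assert ds.sc < dh.sc


class TestInvariances:
    def test_translation_invariance_all(self, ellipse_blob):
        moved = np.roll(np.roll(ellipse_blob, 9, axis=1), -6, axis=0)
        a, b = describe(ellipse_blob), describe(moved)
        assert a.f1 == pytest.approx(b.f1, abs=1e-3)
        assert np.allclose(a.fd, b.fd, atol=1e-3)
        assert a.sc == pytest.approx(b.sc, abs=0.01)
        assert a.sr == pytest.approx(b.sr, abs=0.01)

    def test_scale_invariance_within_1pct(self):
        yy, xx = np.mgrid[0:160, 0:160]
        small = ((xx - 80) / 50.0) ** 2 + ((yy - 80) / 30.0) ** 2 <= 1.0
        yy, xx = np.mgrid[0:320, 0:320]
        big = ((xx - 160) / 100.0) ** 2 + ((yy - 160) / 60.0) ** 2 <= 1.0
        a, b = describe(small), describe(big)
        assert a.f1 == pytest.approx(b.f1, rel=0.01, abs=1e-4)
        assert a.f2 == pytest.approx(b.f2, rel=0.01, abs=1e-4)
        sig = a.fd > 0.01
        assert np.allclose(a.fd[sig], b.fd[sig], rtol=0.01, atol=1e-3)
        assert np.allclose(a.fd[~sig], b.fd[~sig], atol=2e-3)

    @pytest.mark.parametrize("deg", [30, 45, 90])
    def test_rotation_invariance_fd_sr_within_2pct(self, ellipse_blob, deg):
        rot = rotate(ellipse_blob.astype(float), deg, resize=True, order=0) > 0.5
        a, b = describe(ellipse_blob), describe(rot)
        assert b.sr == pytest.approx(a.sr, rel=0.02)
        sig = a.fd > 0.01  # compare harmonics that carry signal
        assert np.allclose(a.fd[sig], b.fd[sig], rtol=0.02, atol=2e-3)
        assert np.allclose(a.fd[~sig], b.fd[~sig], atol=5e-3)
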