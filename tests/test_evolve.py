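import numpy as np
import pytest

from mamseg.errors import (
    ContourVanishedError,
    DegeneratePartitionError,
    GeometryError,
    ParameterError,
)
from mamseg.evolve import (
    ChanVeseParams,
    RegionStats,
    SPFParams,
    evolve_chan_vese,
    evolve_sbgfrls,
    init_levelset,
    mask_from_levelset,
    region_means,
    spf_map,
)
from mamseg.initcontour import manual_contour
from mamseg.metrics import jaccard
from mamseg.pipeline import segment


def circle(cx, cy, r, n=100):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return manual_contour(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))


class TestInitLevelset:
    def test_signed_distance_of_circle(self):
        phi = init_levelset(circle(64, 64, 20), (128, 128))
        assert phi[64, 64] == pytest.approx(20, abs=1.0)
        # |phi| small on the circle
        assert abs(phi[64, 84]) <= 0.8
        area = np.count_nonzero(phi > 0)
        assert area == pytest.approx(np.pi * 400, rel=0.03)

    def test_small_triangle_has_both_signs(self):
        phi = init_levelset(manual_contour([(10, 10), (13, 10), (10, 13)]), (32, 32))
        assert (phi > 0).any() and (phi < 0).any()

    def test_out_of_bounds_contour_rejected(self):
        with pytest.raises(GeometryError):
            init_levelset(circle(10, 10, 30), (32, 32))


class TestRegionMeans:
    def test_two_phase_disk_small_eps(self, two_phase_disk):
        img, truth = two_phase_disk
        phi = init_levelset(circle(64, 64, 35), (128, 128))
        st = region_means(img, phi, eps=0.05)
        assert st.c1 == pytest.approx(0.9, abs=0.01)
        assert st.c2 == pytest.approx(0.2, abs=0.01)

    def test_constant_image(self):
        phi = init_levelset(circle(32, 32, 10), (64, 64))
        st = region_means(np.full((64, 64), 0.4), phi)
        assert st.c1 == pytest.approx(0.4) and st.c2 == pytest.approx(0.4)

    def test_sign_flip_swaps_means(self, two_phase_disk):
        img, _ = two_phase_disk
        phi = init_levelset(circle(64, 64, 35), (128, 128))
        a = region_means(img, phi, eps=0.05)
        b = region_means(img, -phi, eps=0.05)
        assert a.c1 == pytest.approx(b.c2) and a.c2 == pytest.approx(b.c1)


class TestChanVese:
    def test_segments_two_phase_disk_from_loose_init(self, two_phase_disk,
                                                     loose_circle_init):
        img, truth = two_phase_disk
        mask, phi, stats, log = segment(img, loose_circle_init, model="chanvese")
        assert jaccard(truth, mask) >= 0.98
        assert stats.c1 == pytest.approx(0.9, abs=0.01)
        assert stats.c2 == pytest.approx(0.2, abs=0.01)

    def test_zero_mu_nu_on_constant_image_keeps_mask(self):
        img = np.full((64, 64), 0.5)
        phi0 = init_levelset(circle(32, 32, 12), (64, 64))
        p = ChanVeseParams(mu=0.0, nu=0.0, max_iters=50, reinit_every=0)
        phi, _, _ = evolve_chan_vese(img, phi0, p)
        assert np.array_equal(phi > 0, phi0 > 0)

    def test_zero_level_on_true_edge_mu0(self, two_phase_disk, loose_circle_init):
        """mu=nu=0 on a noiseless two-phase image: recovered means within
        1e-3 and the zero level within 1 px of the true edge."""
        from scipy.ndimage import binary_dilation
        img, truth = two_phase_disk
        phi0 = init_levelset(loose_circle_init, img.shape)
        phi, _, _ = evolve_chan_vese(img, phi0, ChanVeseParams(mu=0.0, nu=0.0))
        mask = mask_from_levelset(phi)
        assert img[mask].mean() == pytest.approx(0.9, abs=1e-3)
        assert img[~mask].mean() == pytest.approx(0.2, abs=1e-3)
        sym = mask ^ truth
        edge_band = binary_dilation(truth) & binary_dilation(~truth)
        assert np.all(edge_band[sym])

    def test_lam_weights_change_outcome(self):
        """On an inhomogeneous phantom, lam1=2.5 and lam1=1 give different
        final masks (tuning matters)."""
        from mamseg.phantoms import PhantomSpec, make_phantom, make_manual_init
        ph = make_phantom(PhantomSpec.ill_defined(seed=5))
        init = make_manual_init(ph.truth_contour, 12, shape=ph.image.shape)
        phi0 = init_levelset(init, ph.image.shape)
        a, _, _ = evolve_chan_vese(ph.image, phi0, ChanVeseParams(lam1=2.5, lam2=1.0))
        b, _, _ = evolve_chan_vese(ph.image, phi0, ChanVeseParams(lam1=1.0, lam2=1.0))
        assert not np.array_equal(a > 0, b > 0)

    def test_narrowband_agrees_with_full_domain(self, two_phase_disk,
                                                loose_circle_init):
        img, _ = two_phase_disk
        phi0 = init_levelset(loose_circle_init, img.shape)
        full, _, _ = evolve_chan_vese(img, phi0, ChanVeseParams())
        nb, _, _ = evolve_chan_vese(img, phi0, ChanVeseParams(narrowband=6.0))
        assert jaccard(full > 0, nb > 0) >= 0.99

    def test_contour_vanishes_under_area_pressure(self):
        img = np.full((64, 64), 0.5)
        phi0 = init_levelset(circle(32, 32, 8), (64, 64))
        with pytest.raises(ContourVanishedError) as e:
            evolve_chan_vese(img, phi0, ChanVeseParams(nu=5.0, reinit_every=0))
        assert e.value.iteration > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ChanVeseParams(mu=-1.0)
        with pytest.raises(ParameterError):
            ChanVeseParams(lam1=0.0)


class TestSPF:
    def test_spf_extremes(self):
        img = np.zeros((8, 8))
        img[:4] = 1.0
        spf = spf_map(img, RegionStats(c1=1.0, c2=0.0))
        assert np.all(spf[:4] == 1.0) and np.all(spf[4:] == -1.0)

    def test_spf_normalization_and_bruteforce(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(32, 32))
        st = RegionStats(c1=0.7, c2=0.3)
        spf = spf_map(img, st)
        assert np.abs(spf).max() == pytest.approx(1.0)
        ref = (img - 0.5) / np.abs(img - 0.5).max()
        assert np.allclose(spf, ref, atol=1e-12)
        assert np.all((spf > 0) == (img > 0.5))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            spf_map(np.full((8, 8), 0.5), RegionStats(c1=0.5, c2=0.5))

    def test_segments_two_phase_disk(self, two_phase_disk, loose_circle_init):
        img, truth = two_phase_disk
        mask, _, stats, _ = segment(img, loose_circle_init, model="spf")
        assert jaccard(truth, mask) >= 0.98
        assert stats.c1 == pytest.approx(0.9, abs=0.01)
        assert stats.c2 == pytest.approx(0.2, abs=0.01)

    def test_balloon_grows_from_inside(self, two_phase_disk):
        """Init strictly inside the bright disk: the foreground area grows
        monotonically until it meets the edge."""
        img, truth = two_phase_disk
        phi0 = init_levelset(circle(64, 64, 10), img.shape)
        phi, _, log = evolve_sbgfrls(img, phi0, SPFParams())
        areas = log["area"].to_numpy()
        grow = areas[:10]
        assert np.all(np.diff(grow) >= 0)
        assert areas[-1] == pytest.approx(truth.sum(), rel=0.05)

    def test_deterministic(self, two_phase_disk, loose_circle_init):
        img, _ = two_phase_disk
        phi0 = init_levelset(loose_circle_init, img.shape)
        a, _, _ = evolve_sbgfrls(img, phi0.copy(), SPFParams())
        b, _, _ = evolve_sbgfrls(img, phi0.copy(), SPFParams())
        assert np.array_equal(a, b)


class TestMaskFromLevelset:
    def test_disk_mask(self):
        phi = init_levelset(circle(32, 32, 12), (64, 64))
        mask = mask_from_levelset(phi)
        assert mask.sum() == pytest.approx(np.pi * 144, rel=0.05)

    def test_largest_component_kept(self):
        phi = -np.ones((32, 64))
        phi[10:20, 5:15] = 1.0    # 100 px
        phi[10:14, 40:44] = 1.0   # 16 px
        mask = mask_from_levelset(phi)
        assert mask.sum() == 100 and not mask[10:14, 40:44].any()

    def test_hole_fill_flag(self):
        phi = -np.ones((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(xx - 32, yy - 32)
        phi[(r > 8) & (r < 16)] = 1.0  # annulus
        assert not mask_from_levelset(phi)[32, 32]
        assert mask_from_levelset(phi, fill_holes=True)[32, 32]

    def test_empty_rejected(self):
        with pytest.raises(DegeneratePartitionError):
            mask_from_levelset(-np.ones((8, 8)))
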