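"""Unit and property tests for the gradient and convergence-index filters."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from sbfdetect import (FilterParams, GradientField, compute_gradient,
                       convergence_index, filter_image, sbf_response,
                       tsbf_response)
from sbfdetect.synth import SceneSpec, generate_brightfield_scene

from _oracles import band_filter_brute


def gaussian_bump(H=64, ctr=(32.0, 32.0), sigma=5.0):
    yy, xx = np.mgrid[0:H, 0:H]
    return np.exp(-((yy - ctr[0]) ** 2 + (xx - ctr[1]) ** 2) / (2 * sigma ** 2))


class TestComputeGradient:
    def test_flat_image_has_zero_gradient(self):
        g = compute_gradient(np.full((16, 16), 0.4), smoothing_sigma=0)
        assert np.all(g.gx == 0) and np.all(g.gy == 0)
        assert np.all(g.magnitude == 0)

    def test_column_ramp(self):
        img = np.tile(np.arange(20.0), (10, 1))
        g = compute_gradient(img, smoothing_sigma=0)
        assert np.allclose(g.gx[:, 1:-1], 1.0)
        assert np.allclose(g.gy, 0.0)
        # edge replication halves the one-sided difference at the border
        assert np.allclose(g.gx[:, 0], 0.5)

    def test_magnitude_consistent_with_components(self):
        rng = np.random.default_rng(0)
        g = compute_gradient(rng.random((32, 32)), smoothing_sigma=1.0)
        assert np.allclose(g.magnitude ** 2, g.gx ** 2 + g.gy ** 2)

    def test_gaussian_bump_gradient_matches_analytic_difference(self):
        # central difference of the separable Gaussian has the closed form
        # gx = -2 A(r) B(c) exp(-1/(2 s^2)) sinh(u/s^2), u = c - c0 (and
        # symmetrically for gy); the discrete operator must reproduce its
        # angle to 1e-6 rad, and the field must converge on the bump peak.
        s, ctr = 5.0, (32.0, 32.0)
        img = gaussian_bump(sigma=s, ctr=ctr)
        g = compute_gradient(img, smoothing_sigma=0)
        yy, xx = np.mgrid[0:64, 0:64]
        u, v = xx - ctr[1], yy - ctr[0]
        k = np.exp(-1.0 / (2 * s * s))
        gx_true = -2 * img * k * np.sinh(u / s ** 2)
        gy_true = -2 * img * k * np.sinh(v / s ** 2)
        interior = np.zeros((64, 64), bool)
        interior[1:-1, 1:-1] = True
        interior &= (np.abs(u) + np.abs(v)) > 0
        dang = np.arctan2(g.gy, g.gx) - np.arctan2(gy_true, gx_true)
        dang = np.angle(np.exp(1j * dang))
        assert np.abs(dang[interior]).max() < 1e-6
        # convergence: gradient and direction-to-center nearly parallel
        toward = np.arctan2(-v, -u)
        dev = np.angle(np.exp(1j * (np.arctan2(g.gy, g.gx) - toward)))
        assert np.abs(dev[interior]).max() < 0.15

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            compute_gradient(np.zeros((2, 5)))


class TestConvergenceIndex:
    @staticmethod
    def radial_field(H, ctr, sign):
        yy, xx = np.mgrid[0:H, 0:H]
        vr, vc = ctr[0] - yy, ctr[1] - xx
        n = np.hypot(vr, vc)
        n[n == 0] = 1.0
        gy, gx = sign * vr / n, sign * vc / n
        mag = np.hypot(gx, gy)
        return GradientField(gx=gx, gy=gy, magnitude=mag,
                             angle=np.arctan2(gy, gx))

    @pytest.mark.parametrize("sign,expected", [(+1, 1.0), (-1, -1.0)])
    def test_pure_convergence_and_divergence(self, sign, expected):
        g = self.radial_field(21, (10, 10), sign)
        support = [(r, c) for r in range(21) for c in range(21)
                   if (r, c) != (10, 10)]
        assert convergence_index(g, (10, 10), support) == pytest.approx(expected)

    def test_bright_blob_annulus(self):
        """Dark-field cell model: CI over an annulus of a bright blob ~ 1."""
        img = gaussian_bump()
        g = compute_gradient(img, smoothing_sigma=0)
        yy, xx = np.mgrid[0:64, 0:64]
        d = np.hypot(yy - 32, xx - 32)
        support = [tuple(p) for p in np.argwhere((d >= 3) & (d <= 8))]
        assert convergence_index(g, (32, 32), support) >= 0.99

    def test_empty_support_rejected(self):
        g = self.radial_field(11, (5, 5), 1)
        with pytest.raises(ValueError):
            convergence_index(g, (5, 5), [])


class TestBandResponses:
    def test_flat_image_zero_response(self, small_params):
        g = compute_gradient(np.full((64, 64), 0.5), smoothing_sigma=0)
        assert sbf_response(g, (32, 32), small_params) == 0.0
        assert tsbf_response(g, (32, 32), small_params) == 0.0

    def test_sbf_on_dark_field_blob(self, small_params):
        g = compute_gradient(gaussian_bump(), smoothing_sigma=0)
        assert sbf_response(g, (32, 32), small_params) >= 0.9

    def test_matches_brute_force_oracle(self, smooth_images, small_params):
        rng = np.random.default_rng(7)
        for img in smooth_images[:4]:
            g = compute_gradient(img, smoothing_sigma=0)
            for _ in range(5):
                c = (int(rng.integers(64)), int(rng.integers(64)))
                assert sbf_response(g, c, small_params) == pytest.approx(
                    band_filter_brute(g, c, small_params, "SBF"), abs=1e-12)
                assert tsbf_response(g, c, small_params) == pytest.approx(
                    band_filter_brute(g, c, small_params, "TSBF"), abs=1e-12)

    def test_tsbf_linear_in_contrast(self, small_params):
        rng = np.random.default_rng(3)
        img = ndi.gaussian_filter(rng.random((64, 64)), 2.0)
        g1 = compute_gradient(img, 0)
        g2 = compute_gradient(4.0 * img + 0.25, 0)
        for c in [(20, 20), (40, 31)]:
            r1 = tsbf_response(g1, c, small_params)
            r2 = tsbf_response(g2, c, small_params)
            assert r2 == pytest.approx(4.0 * r1, rel=1e-9)


class TestFilterImage:
    def test_flat_tsbf_map_is_zero(self, small_params):
        rm = filter_image(np.full((48, 48), 0.3), small_params, "TSBF", 0)
        assert np.all(rm.values == 0)

    def test_response_ranges(self, smooth_images, small_params):
        for img in smooth_images[:3]:
            ci = filter_image(img, small_params, "CI", 0).values
            sbf = filter_image(img, small_params, "SBF", 0).values
            tsbf = filter_image(img, small_params, "TSBF", 0).values
            assert ci.min() >= -1 - 1e-12 and ci.max() <= 1 + 1e-12
            assert sbf.min() >= -1 - 1e-12 and sbf.max() <= 1 + 1e-12
            assert tsbf.min() >= 0

    def test_map_agrees_with_point_evaluators(self, smooth_images, small_params):
        img = smooth_images[0]
        g = compute_gradient(img, 0)
        sbf = filter_image(img, small_params, "SBF", 0).values
        tsbf = filter_image(img, small_params, "TSBF", 0).values
        rng = np.random.default_rng(11)
        for _ in range(20):
            c = (int(rng.integers(64)), int(rng.integers(64)))
            assert sbf[c] == pytest.approx(sbf_response(g, c, small_params), abs=1e-12)
            assert tsbf[c] == pytest.approx(tsbf_response(g, c, small_params), abs=1e-12)

    def test_contrast_equivariance(self, smooth_images, small_params):
        img = smooth_images[1]
        base = filter_image(img, small_params, "TSBF", 0).values
        sbf_base = filter_image(img, small_params, "SBF", 0).values
        for a in (0.5, 2.0, 10.0):
            for b in (0.0, 0.1):
                scaled = filter_image(a * img + b, small_params, "TSBF", 0).values
                assert np.allclose(scaled, a * base, rtol=1e-9, atol=1e-12)
            sbf_scaled = filter_image(a * img, small_params, "SBF", 0).values
            assert np.allclose(sbf_scaled, sbf_base, rtol=1e-9, atol=1e-12)

    def test_rotation_symmetry(self, smooth_images):
        # n_lines divisible by 4: the offset table is closed under 90-degree
        # rotation, so the response map of the rotated image is the rotated
        # response map.
        params = FilterParams(r_min=3, r_max=10, n_lines=16, band_width=3)
        img = smooth_images[2]
        r = filter_image(img, params, "TSBF", 0).values
        r90 = filter_image(np.rot90(img), params, "TSBF", 0).values
        assert np.allclose(r90, np.rot90(r), atol=1e-9)

    def test_rejects_undersized_image(self, small_params):
        with pytest.raises(ValueError):
            filter_image(np.zeros((20, 20)), small_params, "TSBF", 0)

    def test_border_mask_marks_clipped_margin(self, small_params):
        rm = filter_image(np.zeros((48, 48)), small_params, "TSBF", 0)
        mask = rm.border_mask()
        m = small_params.border_margin
        assert mask[0, 0] and mask[m - 1, 24]
        assert not mask[m, 24] and not mask[24, 24]

    def test_ring_center_beats_everything_beyond_rmin(self, ring16_clean):
        """Bright-field ring: the planted center out-responds every pixel
        at least r_min away (TSBF enhances the interior, not the ring)."""
        scene = ring16_clean
        rm = filter_image(scene.image, FilterParams(), "TSBF")
        r0, c0 = scene.true_centers[0]
        yy, xx = np.mgrid[0: rm.shape[0], 0: rm.shape[1]]
        far = np.hypot(yy - r0, xx - c0) >= 8
        center_resp = rm.values[int(round(r0)), int(round(c0))]
        assert center_resp > rm.values[far].max()

    def test_scene_localization_envelope(self):
        """In-disc argmax wanders within a small flat-top envelope.

        The discrete radial sampling gives the TSBF a flat-topped peak, so
        the per-cell argmax (within a disc of radius r_min around each
        planted center) drifts by a few pixels but stays well inside the
        NMS window.
        """
        scene = generate_brightfield_scene(SceneSpec(seed=43, n_cells=15))
        rm = filter_image(scene.image, FilterParams(), "TSBF")
        yy, xx = np.mgrid[0:256, 0:256]
        dists = []
        for (r0, c0) in scene.true_centers:
            disc = np.hypot(yy - r0, xx - c0) <= 8
            a = np.unravel_index(
                np.argmax(np.where(disc, rm.values, -np.inf)), rm.shape)
            dists.append(np.hypot(a[0] - r0, a[1] - c0))
        assert max(dists) <= 5.0
        assert np.mean(dists) <= 2.5

    def test_noise_floor_below_cell_centers(self):
        """Pure-noise frames never reach the response of planted centers."""
        empty = generate_brightfield_scene(SceneSpec(n_cells=0, seed=9))
        cells = generate_brightfield_scene(SceneSpec(n_cells=15, seed=43))
        fp = FilterParams()
        noise_max = filter_image(empty.image, fp, "TSBF").values.max()
        rm = filter_image(cells.image, fp, "TSBF").values
        ctrs = np.round(cells.true_centers).astype(int)
        assert noise_max < rm[ctrs[:, 0], ctrs[:, 1]].min()


class TestFilterParams:
    @pytest.mark.parametrize("kw", [
        dict(r_min=0), dict(r_max=8, r_min=8), dict(n_lines=3),
        dict(band_width=0), dict(band_width=24, r_min=8, r_max=30),
        dict(omega=-0.5),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            FilterParams(**kw)

    def test_defaults_match_study_settings(self):
        p = FilterParams()
        assert (p.r_min, p.r_max, p.n_lines, p.band_width, p.omega) == \
            (8, 30, 32, 6, 1.0)
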