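"""Enhancement filter: DT, adaptive radius, Hessian, response, pseudo-labels.

Each numerical stage is checked against an independent brute-force oracle
(exhaustive distance minimization, explicit convolution sums with a
closed-form symmetric 3×3 eigensolver, exhaustive-threshold Otsu).
"""

import numpy as np
import pytest

from neuroseg import (EnhancerParams, PhantomConfig, adaptive_radius,
                      apply_transform, distance_transform, enhance_volume,
                      generate_phantom, hessian_eigen, make_pseudolabels,
                      normalize_dt, seg_metrics, soma_fill,
                      vesselness_response)
from neuroseg.enhance import EnhancerConfigError, gaussian_derivative_kernels
from oracles import brute_force_dt, brute_force_otsu, symmetric_eig3


# ---------------------------------------------------------------------------
# distance transform
# ---------------------------------------------------------------------------

class TestDistanceTransform:
    def test_all_background_is_zero(self):
        vol = np.zeros((6, 6, 6), dtype=np.uint8)
        np.testing.assert_array_equal(distance_transform(vol, 40), 0.0)

    def test_single_voxel_distance_one(self):
        vol = np.zeros((7, 7, 7), dtype=np.uint8)
        vol[3, 3, 3] = 200
        dt = distance_transform(vol, 40)
        assert dt[3, 3, 3] == 1.0
        assert dt.sum() == 1.0

    def test_solid_cube_center(self):
        vol = np.zeros((11, 11, 11), dtype=np.uint8)
        vol[3:8, 3:8, 3:8] = 200
        dt = distance_transform(vol, 40)
        assert dt[5, 5, 5] == 3.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        vol = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8) * 200
        dt = distance_transform(vol, 40)
        np.testing.assert_allclose(dt, brute_force_dt(vol >= 40), atol=1e-12)

    def test_all_foreground_uses_virtual_border(self):
        vol = np.full((9, 9, 9), 200, dtype=np.uint8)
        dt = distance_transform(vol, 40)
        assert dt[4, 4, 4] == 5.0  # to the virtual background just outside
        assert dt[0, 0, 0] == 1.0


class TestNormalizeDT:
    def test_degenerate_span_maps_to_one(self):
        dt = np.zeros((4, 4, 4))
        dt[1:3, 1:3, 1:3] = 1.0
        np.testing.assert_array_equal(normalize_dt(dt), 1.0)

    def test_endpoints_and_midpoint(self):
        dt = np.zeros((1, 1, 5))
        dt[0, 0, :3] = [1.0, 5.0, 3.0]
        dn = normalize_dt(dt)
        assert dn[0, 0, 0] == 1.0
        assert dn[0, 0, 1] == 256.0
        assert dn[0, 0, 2] == pytest.approx(128.5)
        assert dn[0, 0, 3] == 1.0  # background


class TestAdaptiveRadius:
    @pytest.mark.parametrize("dn,r,di", [(256.0, 8, 17), (1.0, 1, 3), (16.0, 4, 9)])
    def test_radius_formula(self, dn, r, di):
        rr, dd = adaptive_radius(np.array([[[dn]]]))
        assert rr[0, 0, 0] == r
        assert dd[0, 0, 0] == di

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adaptive_radius(np.array([[[300.0]]]))


# ---------------------------------------------------------------------------
# Hessian eigenvalues
# ---------------------------------------------------------------------------

class TestHessianEigen:
    def test_constant_volume_all_zero(self):
        vol = np.full((9, 9, 9), 80.0)
        eigs = hessian_eigen(vol, 2)
        np.testing.assert_allclose(eigs, 0.0, atol=1e-10)

    def test_bright_ridge_eigen_structure(self):
        """I = −(y² + x²): a bright line along z → λ1 ≈ 0, λ2 ≈ λ3 < 0."""
        n = 17
        c = n // 2
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        vol = np.broadcast_to(-(yy**2 + xx**2).astype(float), (n, n, n)).copy()
        eigs = hessian_eigen(vol, 2)
        interior = eigs[4:-4, 4:-4, 4:-4].reshape(-1, 3)
        l1, l2, l3 = interior[:, 0], interior[:, 1], interior[:, 2]
        assert np.abs(l1).max() < 0.05 * np.abs(l3).min()
        assert (l2 < 0).all() and (l3 < 0).all()
        np.testing.assert_allclose(l2, l3, rtol=1e-6)

    def test_matches_bruteforce_convolution_and_eigensolve(self):
        """Filter output = explicit convolution sums + closed-form eigen."""
        rng = np.random.default_rng(3)
        vol = rng.random((9, 9, 9)) * 255
        radius = 2
        sigma = radius / 2.0
        eigs = hessian_eigen(vol, radius)

        k0, k1, k2 = gaussian_derivative_kernels(sigma, radius)
        kernels = {0: k0, 1: k1, 2: k2}
        orders = {"zz": (2, 0, 0), "zy": (1, 1, 0), "zx": (1, 0, 1),
                  "yy": (0, 2, 0), "yx": (0, 1, 1), "xx": (0, 0, 2)}
        comps = {}
        for name, (oz, oy, ox) in orders.items():
            kern = (kernels[oz][:, None, None] * kernels[oy][None, :, None]
                    * kernels[ox][None, None, :])
            out = np.zeros_like(vol)
            for z in range(radius, 9 - radius):      # interior: padding-free
                for y in range(radius, 9 - radius):
                    for x in range(radius, 9 - radius):
                        acc = 0.0
                        for dz in range(-radius, radius + 1):
                            for dy in range(-radius, radius + 1):
                                for dx in range(-radius, radius + 1):
                                    acc += kern[dz + radius, dy + radius, dx + radius] \
                                        * vol[z + dz, y + dy, x + dx]
                        out[z, y, x] = acc * sigma**2
            comps[name] = out

        for z in range(3, 6):
            for y in range(3, 6):
                for x in range(3, 6):
                    h = np.array([
                        [comps["zz"][z, y, x], comps["zy"][z, y, x], comps["zx"][z, y, x]],
                        [comps["zy"][z, y, x], comps["yy"][z, y, x], comps["yx"][z, y, x]],
                        [comps["zx"][z, y, x], comps["zx"][z, y, x] * 0 + comps["yx"][z, y, x], comps["xx"][z, y, x]],
                    ])
                    ref = symmetric_eig3(h)
                    ref = ref[np.argsort(np.abs(ref))]
                    np.testing.assert_allclose(eigs[z, y, x], ref, atol=1e-6)

    def test_sorted_by_absolute_value(self, rng):
        vol = rng.random((9, 9, 9)) * 255
        eigs = hessian_eigen(vol, 1)
        mags = np.abs(eigs)
        assert (mags[..., 0] <= mags[..., 1] + 1e-12).all()
        assert (mags[..., 1] <= mags[..., 2] + 1e-12).all()


# ---------------------------------------------------------------------------
# response function
# ---------------------------------------------------------------------------

class TestVesselnessResponse:
    def test_positive_eigenvalue_gate(self):
        assert vesselness_response(np.array([0.0, 1.0, -2.0])) == 0.0

    def test_ideal_plate_no_response(self):
        assert vesselness_response(np.array([0.0, 0.0, -10.0])) == 0.0

    def test_ideal_line_closed_form(self):
        val = vesselness_response(np.array([0.0, -1000.0, -1000.0]))
        expected = (1.0 - np.exp(-5.55)) * 1.0 * (1.0 - np.exp(-2e6 / 2e6))
        assert val == pytest.approx(expected, abs=1e-9)
        assert val == pytest.approx(0.6297, abs=5e-4)

    def test_scale_gating_monotone(self):
        base = np.array([-1.0, -30.0, -40.0])
        prev = -1.0
        for t in (1.0, 2.0, 5.0, 20.0):
            r = float(vesselness_response(base * t))
            assert r >= prev - 1e-12
            prev = r

    def test_ratio_invariance_of_p1_p2(self):
        # with the p3 factor saturated, scaling leaves the response unchanged
        big = np.array([-1e4, -3e5, -4e5])
        r1 = float(vesselness_response(big))
        r2 = float(vesselness_response(big * 3.0))
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_p2_literal_toggle_changes_value(self):
        lam = np.array([-0.5, -2.0, -2.5])
        a = float(vesselness_response(lam))
        b = float(vesselness_response(lam, EnhancerParams(p2_literal=True)))
        assert a != b


# ---------------------------------------------------------------------------
# soma filling and the full pipeline
# ---------------------------------------------------------------------------

class TestSomaFill:
    def _ball(self, n=21, r=6, level=250):
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        d2 = zz**2 + yy**2 + xx**2
        vol = np.full((n, n, n), 10.0)
        vol[d2 <= r**2] = level
        return vol, d2

    def test_no_bright_voxels_is_identity(self):
        vol = np.full((8, 8, 8), 100.0)
        enhanced = np.random.default_rng(0).random((8, 8, 8)) * 50
        out, soma = soma_fill(enhanced, vol, EnhancerParams())
        np.testing.assert_array_equal(out, enhanced)
        assert not soma.any()

    def test_ball_interior_filled_ring_kept(self):
        vol, d2 = self._ball()
        enhanced = np.full(vol.shape, 7.0)
        params = EnhancerParams(soma_dt_threshold=3.0)
        out, soma = soma_fill(enhanced, vol, params)
        dt2 = distance_transform(vol, params.soma_threshold_i2)
        np.testing.assert_array_equal(out[dt2 > 3.0], 255.0)
        np.testing.assert_array_equal(out[dt2 <= 3.0], 7.0)
        assert soma.sum() > 0

    def test_infinite_threshold_is_identity(self):
        vol, _ = self._ball()
        enhanced = np.full(vol.shape, 7.0)
        out, _ = soma_fill(enhanced, vol, EnhancerParams(soma_dt_threshold=np.inf))
        np.testing.assert_array_equal(out, enhanced)

    def test_i2_must_exceed_i1(self):
        with pytest.raises(EnhancerConfigError):
            EnhancerParams(fg_threshold_i1=150, soma_threshold_i2=100).validate()


class TestEnhanceVolume:
    def test_tube_enhanced_above_background(self, small_phantom):
        image, mask = small_phantom
        o = enhance_volume(image)
        assert o[mask > 0].mean() > 5 * o[mask == 0].mean()

    def test_empty_scene_near_zero(self):
        cfg = PhantomConfig(shape=(32, 32, 32), n_neurites=0, n_somata=0,
                            noise_sigma=0.0, illumination_gradient=0.0, seed=2)
        image, _ = generate_phantom(cfg)
        o = enhance_volume(image)
        assert o.max() <= 1e-6

    def test_soma_interior_filled(self):
        cfg = PhantomConfig(shape=(40, 40, 40), n_neurites=2, n_somata=2,
                            noise_sigma=0.0, seed=12)
        image, _ = generate_phantom(cfg)
        params = EnhancerParams()
        o = enhance_volume(image, params)
        d2 = distance_transform(image, params.soma_threshold_i2)
        assert (d2 > params.soma_dt_threshold).any()
        np.testing.assert_array_equal(o[d2 > params.soma_dt_threshold], 255.0)

    def test_equivariance_under_rotation(self, small_phantom):
        image, _ = small_phantom
        a = enhance_volume(apply_transform(image, "rot90_xy"))
        b = apply_transform(enhance_volume(image), "rot90_xy")
        core = (slice(4, -4),) * 3
        np.testing.assert_allclose(a[core], b[core], atol=1e-6)


class TestPseudoLabels:
    def test_bimodal_split(self):
        o = np.zeros((4, 4, 4))
        o[2:] = 255.0
        mask = make_pseudolabels(o)
        np.testing.assert_array_equal(mask, (o == 255).astype(np.uint8))

    def test_constant_gives_empty(self):
        assert make_pseudolabels(np.zeros((4, 4, 4))).sum() == 0

    def test_otsu_matches_bruteforce(self, rng):
        vals = np.concatenate([rng.normal(30, 5, 2000), rng.normal(200, 5, 500)])
        o = np.clip(vals, 0, 255).reshape(10, 10, 25)
        mask = make_pseudolabels(np.rint(o))
        t = brute_force_otsu(np.rint(o))
        assert 30 < t < 200
        np.testing.assert_array_equal(mask, (np.rint(o) > t).astype(np.uint8))

    def test_fixed_threshold_mode(self):
        o = np.arange(64, dtype=float).reshape(4, 4, 4) * 4
        params = EnhancerParams(pseudo_label_method="fixed", pseudo_label_value=100.0)
        mask = make_pseudolabels(o, params)
        np.testing.assert_array_equal(mask, (o >= 100.0).astype(np.uint8))

    def test_pseudolabel_f1_floor_on_noiseless_phantom(self):
        cfg = PhantomConfig(noise_sigma=0.0, seed=21)
        image, gt = generate_phantom(cfg)
        pl = make_pseudolabels(enhance_volume(image))
        assert seg_metrics(pl, gt).f1 >= 0.6
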