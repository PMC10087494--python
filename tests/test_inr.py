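"""INR machinery: activations, encoders, MLPs, differentiable warping."""

import numpy as np
import pytest

from stinr.inr import (Adam, GRFFEncoder, MLP, SpatialINR, TemporalINR,
                       SCALED_PRESET, swish, swish_grad)
from stinr.volume import make_volume
from stinr.warp import (trilinear_gather, trilinear_gather_grad,
                        trilinear_scatter, warp_backward, warp_volume)


class TestSwish:
    def test_closed_form_values(self):
        assert swish(0.0) == 0.0
        assert swish(1.0) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))
        assert swish(1.0) == pytest.approx(0.7310586, abs=1e-6)

    def test_approaches_identity_for_large_inputs(self):
        assert swish(50.0) / 50.0 == pytest.approx(1.0, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        y = np.linspace(-4, 4, 17)
        eps = 1e-6
        fd = (swish(y + eps) - swish(y - eps)) / (2 * eps)
        assert np.allclose(swish_grad(y), fd, atol=1e-8)


class TestGRFFEncoder:
    def test_zero_input_gives_sin_zero_cos_one(self):
        enc = GRFFEncoder(3, n_features=16, seed=0)
        out = enc.encode(np.zeros((4, 3)))
        assert np.allclose(out[:, :16], 0.0)
        assert np.allclose(out[:, 16:], 1.0)

    def test_outputs_bounded(self):
        enc = GRFFEncoder(3, n_features=32, sigma_b=4.0, seed=1)
        out = enc.encode(np.random.default_rng(0).uniform(-1, 1, (100, 3)))
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_seeded_determinism(self):
        a = GRFFEncoder(2, 16, 2.5, seed=9)
        b = GRFFEncoder(2, 16, 2.5, seed=9)
        x = np.random.default_rng(1).normal(size=(10, 2))
        assert np.array_equal(a.B, b.B)
        assert np.array_equal(a.encode(x), b.encode(x))

    def test_output_dim_is_twice_feature_count(self):
        enc = GRFFEncoder(1, n_features=128)
        assert enc.out_dim == 256
        assert enc.encode(np.zeros((3, 1))).shape == (3, 256)


class TestSpatialINR:
    def _inr(self, seed=0):
        return SpatialINR(np.zeros(3), np.full(3, 48.0), seed=seed)

    def test_identical_coordinates_identical_outputs(self):
        inr = self._inr()
        pts = np.array([[1.0, -2.0, 3.0], [1.0, -2.0, 3.0]])
        out = inr.eval_points(pts)
        assert out[0] == out[1]

    def test_overfits_smooth_random_volume(self):
        """Capacity check: 500 voxelwise fit steps shrink the SSD >= 10x,
        and the fitted representation renders consistently across grids."""
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(3)
        target = gaussian_filter(rng.normal(size=(32, 32, 32)), 4.0)
        target = (target / np.abs(target).max() * 0.02).astype(np.float32)
        inr = SpatialINR(np.zeros(3), np.full(3, 48.0), seed=1)
        shape, spacing = (32, 32, 32), 3.0
        from stinr.volume import centered_grid
        origin = centered_grid(shape, np.full(3, spacing))
        axes = [origin[a] + spacing * np.arange(32) for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([a.ravel() for a in g], axis=1)
        tgt = target.ravel()
        opt = Adam(inr.mlp.params(), lr=0.002)
        vals, cache = inr.eval_points(pts, want_cache=True)
        ssd0 = float(np.sum((vals - tgt) ** 2))
        for _ in range(300):
            vals, cache = inr.eval_points(pts, want_cache=True)
            grads = inr.backward(cache, 2.0 * (vals - tgt) / len(tgt))
            opt.step(inr.mlp.params(), grads)
        ssd = float(np.sum((inr.eval_points(pts) - tgt) ** 2))
        assert ssd <= ssd0 / 10.0
        # arbitrary-resolution inference: the 32^3 rendering block-averaged
        # to 16^3 agrees with a direct 16^3 query of the same function
        hi = inr.eval_grid((32, 32, 32), 3.0)
        lo = inr.eval_grid((16, 16, 16), 6.0)
        down = hi.reshape(16, 2, 16, 2, 16, 2).mean(axis=(1, 3, 5))
        rms = lambda a: float(np.sqrt(np.mean(a ** 2)))
        assert rms(down - lo) <= 0.15 * rms(lo)

    def test_parameter_gradients_match_finite_differences(self):
        inr = self._inr(seed=5)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-40, 40, size=(20, 3))
        dvals = rng.normal(size=20)
        vals, cache = inr.eval_points(pts, want_cache=True)
        grads = inr.backward(cache, dvals)
        params = inr.mlp.params()
        eps = 1e-2
        for pi in (0, 3, 4, 7):
            idx = tuple(rng.integers(0, s) for s in params[pi].shape)
            orig = params[pi][idx].copy()
            params[pi][idx] = orig + eps
            lp = float(np.sum(inr.eval_points(pts).astype(np.float64) * dvals))
            params[pi][idx] = orig - eps
            lm = float(np.sum(inr.eval_points(pts).astype(np.float64) * dvals))
            params[pi][idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(fd, rel=1e-2, abs=1e-7)


class TestTemporalINR:
    def test_identical_times_identical_weights(self):
        ti = TemporalINR(seed=2)
        w = ti.eval_times([0.3, 0.3])
        assert np.array_equal(w[0], w[1])
        assert w.shape == (2, 9)

    def test_rejects_times_outside_unit_interval(self):
        ti = TemporalINR(seed=2)
        with pytest.raises(ValueError):
            ti.eval_times([1.5])

    def test_fits_known_sinusoidal_track(self):
        ti = TemporalINR(seed=3)
        t = np.linspace(0, 1, 110)
        target = np.sin(2 * np.pi * 4 * t) * 1.5
        params = ti.params()
        opt = Adam(params, lr=0.002)
        for _ in range(500):
            w, caches = ti.eval_times(t, want_cache=True)
            dw = np.zeros_like(w, dtype=np.float64)
            dw[:, 4] = 2.0 * (w[:, 4] - target) / len(t)
            opt.step(params, ti.backward(caches, dw))
        w = ti.eval_times(t)
        r = np.corrcoef(w[:, 4], target)[0, 1]
        assert r >= 0.99

    def test_sub_mlps_are_independent(self):
        ti = TemporalINR(seed=4)
        for m in ti.mlps:       # give every head a nonzero output path
            m.W[-1][:] = 0.01
        t = np.linspace(0, 1, 7)
        before = ti.eval_times(t)
        ti.mlps[2].W[0] += 0.5  # perturb one sub-MLP only
        after = ti.eval_times(t)
        changed = np.any(before != after, axis=0)
        assert changed[2]
        assert not changed[[0, 1, 3, 4, 5, 6, 7, 8]].any()

    def test_weights_start_at_zero(self):
        ti = TemporalINR(seed=5)
        assert np.allclose(ti.eval_times(np.linspace(0, 1, 5)), 0.0)


class TestWarp:
    def _vol(self):
        rng = np.random.default_rng(0)
        return make_volume(rng.random((10, 10, 10)), 2.0)

    def test_zero_displacement_is_identity(self):
        vol = self._vol()
        out = warp_volume(vol, np.zeros((10, 10, 10, 3)))
        assert np.allclose(out.data, vol.data)

    def test_one_voxel_si_shift_exact_in_interior(self):
        vol = self._vol()
        dvf = np.zeros((10, 10, 10, 3))
        dvf[..., 2] = 2.0  # one voxel along SI
        out = warp_volume(vol, dvf)
        assert np.allclose(out.data[:, :, :-1], vol.data[:, :, 1:], atol=1e-12)

    def test_out_of_bounds_clamps_without_nans(self):
        vol = self._vol()
        dvf = np.full((10, 10, 10, 3), 100.0)
        out = warp_volume(vol, dvf)
        assert np.all(np.isfinite(out.data))
        assert out.data[0, 0, 0] == vol.data[-1, -1, -1]

    def test_scatter_is_adjoint_of_gather(self):
        rng = np.random.default_rng(1)
        vol = rng.random((6, 6, 6))
        pts = rng.uniform(0, 5, size=(40, 3))
        vals = rng.random(40)
        lhs = float(np.sum(trilinear_gather(vol, pts) * vals))
        rhs = float(np.sum(vol * trilinear_scatter(6, 6, 6, pts, vals)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_position_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        vol = rng.random((8, 8, 8))
        pts = rng.uniform(1.0, 6.0, size=(15, 3))
        g = trilinear_gather_grad(vol, pts)
        eps = 1e-6
        for a in range(3):
            pp = pts.copy()
            pp[:, a] += eps
            pm = pts.copy()
            pm[:, a] -= eps
            fd = (trilinear_gather(vol, pp) - trilinear_gather(vol, pm)) \
                / (2 * eps)
            assert np.allclose(g[:, a], fd, atol=1e-6)

    def test_warp_backward_chains_spacing(self):
        rng = np.random.default_rng(3)
        vol = rng.random((8, 8, 8))
        pts = rng.uniform(1.0, 6.0, size=(12, 3))
        dout = rng.random(12)
        d_vol, d_dvf = warp_backward(vol, np.array([2.0, 2.0, 2.0]), pts, dout)
        g = trilinear_gather_grad(vol, pts)
        assert np.allclose(d_dvf, g * dout[:, None] / 2.0)
        assert d_vol.shape == vol.shape
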