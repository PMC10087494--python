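"""Dynamic CBCT reconstructors.

Three methods share the projector/motion-model contract:

* ``stinr_fit`` — joint spatial + temporal INR learning in three stages:
  (1) fit the spatial INR to an FDK volume of the end-expiration (EE)
  projection subset, (2) fine-tune it on the EE projections through the
  forward projector, (3) jointly optimize the spatial INR and the nine
  temporal INRs against all projections, with the deformation composed from
  the PCA motion model.
* ``pca_cv_fit`` — the conventional PCA-driven baseline: a fixed reference
  volume (ART+TV from the EE subset) plus an independent per-projection
  nonlinear conjugate-gradient fit of the 9 component weights.
* ``inr_poly_fit`` — a spatial INR with voxel-wise motion coefficients
  weighted by temporal polynomials (no motion prior).

All optimization is seeded and deterministic; loss traces are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import (ProjectionSet, ScanGeometry, fdk_reconstruct,
                       project_view, backproject_view)
from .inr import Adam, SpatialINR, TemporalINR, SCALED_PRESET
from .motion import MotionModel, WeightTrack, compose_dvf
from .volume import Volume, make_volume, centered_grid
from .warp import trilinear_gather, warp_backward

__all__ = [
    "StinrConfig", "StinrResult", "ArtTvConfig", "PolyMotionConfig",
    "extract_ee_projections", "stinr_fit", "stinr_infer",
    "art_tv_reconstruct", "pca_cv_fit", "inr_poly_fit",
]


# ---------------------------------------------------------------------------
# EE-phase extraction
# ---------------------------------------------------------------------------

def extract_ee_projections(projections: ProjectionSet, signal, fraction=0.1):
    """Frames whose breathing signal lies in the lowest ``fraction`` quantile.

    Selection keeps exactly ``round(fraction * n)`` frames (stable sort by
    signal), preserving angles and timestamps.  A constant signal is
    degenerate: all frames are returned with a warning.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) != len(projections):
        raise ValueError("signal must align with the projection frames")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(projections)
    if np.ptp(signal) < 1e-12:
        warnings.warn("constant breathing signal: EE selection is degenerate; "
                      "keeping all frames")
        idx = np.arange(n)
    else:
        k = max(1, int(round(fraction * n)))
        idx = np.sort(np.argsort(signal, kind="stable")[:k])
    if len(idx) == 0:
        raise ValueError("EE selection is empty")
    return projections.subset(idx), idx


# ---------------------------------------------------------------------------
# STINR
# ---------------------------------------------------------------------------

@dataclass
class StinrConfig:
    """Hyper-parameters of the three-stage fit.

    Iteration defaults follow the published schedule (500 / 500 / 4000 at
    learning rate 0.002); desk-scale runs shrink ``stage3_iters`` and the
    grids.  ``opt_shape``/``opt_spacing`` define the voxelized intermediate
    grid used during optimization; inference may use any grid.
    """

    stage1_iters: int = 500
    stage2_iters: int = 500
    stage3_iters: int = 4000
    lr: float = 0.002
    batch_frames: int = 8
    opt_shape: tuple = (64, 64, 64)
    opt_spacing: float = 6.0
    preset: dict = field(default_factory=lambda: dict(SCALED_PRESET))
    seed: int = 0
    ee_fraction: float = 0.1
    activation: str = "swish"

    def __post_init__(self):
        if min(self.stage1_iters, self.stage2_iters, self.stage3_iters) < 0:
            raise ValueError("iteration counts must be >= 0")
        if min(self.opt_shape) <= 0 or self.opt_spacing <= 0:
            raise ValueError("grids must be positive")


@dataclass
class StinrResult:
    spatial: SpatialINR
    temporal: TemporalINR
    model: MotionModel           # resampled to the optimization grid
    config: StinrConfig
    loss_trace: dict             # stage name -> per-iteration loss array
    t0: float
    t1: float                    # time-normalization window (s)

    def normalize_times(self, times):
        t = (np.asarray(times, dtype=np.float64) - self.t0) \
            / max(self.t1 - self.t0, 1e-12)
        return np.clip(t, 0.0, 1.0)


def _grid_points_mm(shape, spacing, origin):
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def _opt_grid(config: StinrConfig):
    shape = tuple(int(s) for s in config.opt_shape)
    spacing = np.array([config.opt_spacing] * 3, dtype=np.float64)
    origin = centered_grid(shape, spacing)
    return shape, spacing, origin


def _prepare_model(model: MotionModel, shape, spacing, origin):
    if model.grid_shape == shape and np.allclose(model.spacing, spacing):
        return model
    return model.resampled(shape, spacing, origin)


def _ray_step(spacing):
    return 0.5 * float(np.min(spacing))


def stinr_fit(projections: ProjectionSet, model: MotionModel,
              config: StinrConfig, signal=None) -> StinrResult:
    """Three-stage joint fit of the spatial and temporal INRs.

    ``signal`` is the per-frame breathing surrogate used for EE extraction
    (stages 1-2); when omitted, stages 1-2 use all frames.
    """
    shape, spacing, origin = _opt_grid(config)
    model = _prepare_model(model, shape, spacing, origin)
    geom = projections.geometry
    step = _ray_step(spacing)
    half = np.asarray(shape) * spacing / 2.0

    spatial = SpatialINR(np.zeros(3), half, preset=config.preset,
                         seed=config.seed, activation=config.activation)
    temporal = TemporalINR(preset=config.preset, seed=config.seed + 1000,
                           activation=config.activation)
    t0 = float(projections.times_s.min())
    t1 = float(projections.times_s.max())
    result = StinrResult(spatial, temporal, model, config, {}, t0, t1)

    if signal is not None:
        ee, _ = extract_ee_projections(projections, signal,
                                       config.ee_fraction)
    else:
        ee = projections

    pts_mm = _grid_points_mm(shape, spacing, origin)
    enc_grid = spatial.encode_points(pts_mm)  # frozen features, fixed grid
    rng = np.random.default_rng(config.seed + 7)
    n_vox = pts_mm.shape[0]

    # ---- stage 1: voxelwise fit to the EE FDK volume -----------------------
    grid_vol = make_volume(np.zeros(shape, dtype=np.float32), spacing, origin)
    fdk = fdk_reconstruct(ee, grid_vol)
    target = fdk.data.ravel().astype(np.float32)
    opt = Adam(spatial.mlp.params(), lr=config.lr)
    trace1 = np.empty(config.stage1_iters)
    for it in range(config.stage1_iters):
        vals, cache = spatial.eval_encoded(enc_grid, want_cache=True)
        resid = vals - target
        trace1[it] = float(np.mean(resid ** 2))
        grads = spatial.backward(cache, 2.0 * resid / n_vox)
        opt.step(spatial.mlp.params(), grads)
    result.loss_trace["stage1"] = trace1

    # ---- stage 2: fine-tune on EE projections ------------------------------
    trace2 = np.empty(config.stage2_iters)
    opt = Adam(spatial.mlp.params(), lr=config.lr)
    for it in range(config.stage2_iters):
        opt.set_lr_fraction(it / max(config.stage2_iters - 1, 1))
        sel = rng.choice(len(ee), size=min(config.batch_frames, len(ee)),
                         replace=False)
        vals, cache = spatial.eval_encoded(enc_grid, want_cache=True)
        sigma = vals.reshape(shape).astype(np.float64)
        d_sigma = np.zeros(shape)
        loss = 0.0
        for f in sel:
            drr = project_view(sigma, spacing, origin, geom,
                               ee.angles_deg[f], step)
            resid = drr - ee.images[f]
            loss += float(np.sum(resid ** 2))
            d_sigma += backproject_view(2.0 * resid, shape, spacing, origin,
                                        geom, ee.angles_deg[f], step)
        trace2[it] = loss / len(sel)
        grads = spatial.backward(cache, d_sigma.ravel() / len(sel))
        opt.step(spatial.mlp.params(), grads)
    result.loss_trace["stage2"] = trace2

    # ---- stage 3: joint spatial + temporal fit on all projections ----------
    # initialize the temporal INRs at the weights that cancel the mean
    # motion component, so the composed displacement starts at zero --
    # consistent with the static-anatomy assumption of stages 1-2 and
    # avoiding an early-training drift of the reference volume
    from .motion import project_dvf_to_weights
    w_zero = project_dvf_to_weights(model, np.zeros_like(model.pc0))
    for j, sub in enumerate(temporal.mlps):
        sub.b[-1][:] = np.float32(w_zero[j])

    base_idx = (pts_mm - origin) / spacing  # (N, 3) voxel coords of the grid
    t_norm = result.normalize_times(projections.times_s)
    n_frames = len(projections)
    n_comp = model.n_components
    comps_flat = model.components.reshape(3, n_comp, -1)
    pc0_flat = model.pc0.reshape(-1, 3)

    params_s = spatial.mlp.params()
    params_t = temporal.params()
    opt_s = Adam(params_s, lr=config.lr)
    opt_t = Adam(params_t, lr=config.lr)
    trace3 = np.empty(config.stage3_iters)
    for it in range(config.stage3_iters):
        frac = it / max(config.stage3_iters - 1, 1)
        opt_s.set_lr_fraction(frac)
        opt_t.set_lr_fraction(frac)
        sel = rng.choice(n_frames, size=min(config.batch_frames, n_frames),
                         replace=False)
        vals, cache_s = spatial.eval_encoded(enc_grid, want_cache=True)
        sigma = vals.reshape(shape).astype(np.float64)
        w_batch, cache_t = temporal.eval_times(t_norm[sel], want_cache=True)
        d_sigma = np.zeros(shape)
        d_w = np.zeros_like(w_batch, dtype=np.float64)
        loss = 0.0
        for bi, f in enumerate(sel):
            w = w_batch[bi].reshape(3, n_comp)
            dvf = pc0_flat.copy()
            for d in range(3):
                dvf[:, d] += w[d] @ comps_flat[d]
            pts = base_idx + dvf / spacing
            warped = trilinear_gather(sigma, pts).reshape(shape)
            drr = project_view(warped, spacing, origin, geom,
                               projections.angles_deg[f], step)
            resid = drr - projections.images[f]
            loss += float(np.sum(resid ** 2))
            g_warped = backproject_view(2.0 * resid, shape, spacing, origin,
                                        geom, projections.angles_deg[f], step)
            dv, d_dvf = warp_backward(sigma, spacing, pts, g_warped.ravel())
            d_sigma += dv
            for d in range(3):
                d_w[bi, n_comp * d:n_comp * (d + 1)] = \
                    comps_flat[d] @ d_dvf[:, d]
        trace3[it] = loss / len(sel)
        if not np.isfinite(trace3[it]):
            raise FloatingPointError(
                f"stage-3 loss diverged at iteration {it}")
        grads_s = spatial.backward(cache_s, d_sigma.ravel() / len(sel))
        grads_t = temporal.backward(cache_t, d_w / len(sel))
        opt_s.step(params_s, grads_s)
        opt_t.step(params_t, grads_t)
    result.loss_trace["stage3"] = trace3
    return result


def stinr_infer(result: StinrResult, times, shape=None, spacing=None,
                clip_negative=True):
    """Render dynamic volumes at arbitrary times and grid resolution.

    Returns ``(volumes, weight_track, dvfs)``: for each time, the temporal
    INRs give the 9 weights, the motion model composes the DVF, and the
    spatial-INR-rendered reference is warped into the frame.
    """
    cfg = result.config
    if shape is None:
        shape = cfg.opt_shape
    shape = tuple(int(s) for s in shape)
    if spacing is None:
        spacing = np.asarray(cfg.opt_shape) * cfg.opt_spacing / np.asarray(shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    origin = centered_grid(shape, spacing)
    model = _prepare_model(result.model, shape, spacing, origin)
    times = np.atleast_1d(np.asarray(times, dtype=np.float64))
    w_all = result.temporal.eval_times(result.normalize_times(times))
    sigma = result.spatial.eval_grid(shape, spacing, origin).astype(np.float64)
    if clip_negative:
        sigma = np.clip(sigma, 0.0, None)
    ref = make_volume(sigma.astype(np.float32), spacing, origin)
    base_idx = (_grid_points_mm(shape, spacing, origin) - origin) / spacing
    volumes, dvfs = [], []
    for i in range(len(times)):
        dvf = compose_dvf(model, w_all[i])
        pts = base_idx + dvf.reshape(-1, 3) / spacing
        warped = trilinear_gather(sigma, pts).reshape(shape)
        volumes.append(make_volume(warped.astype(np.float32), spacing, origin))
        dvfs.append(dvf)
    return volumes, WeightTrack(times, w_all), ref, dvfs


# ---------------------------------------------------------------------------
# ART + TV (reference volume for the conventional PCA baseline)
# ---------------------------------------------------------------------------

@dataclass
class ArtTvConfig:
    relaxation: float = 0.4       # lambda in (0, 2)
    sweeps: int = 20              # ART/TV alternations
    tv_steps: int = 10            # TV descent steps per alternation
    tv_step_scale: float = 0.1    # TV step as fraction of the ART update norm
    tol: float = 0.0              # stop when the sweep update falls below tol

    def __post_init__(self):
        if not 0 < self.relaxation < 2:
            raise ValueError("relaxation must lie in (0, 2)")


def _tv_gradient(mu, eps=1e-7):
    """Gradient of the smoothed isotropic TV norm (forward differences)."""
    gx = np.diff(mu, axis=0, append=mu[-1:])
    gy = np.diff(mu, axis=1, append=mu[:, -1:])
    gz = np.diff(mu, axis=2, append=mu[:, :, -1:])
    mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2 + eps)
    px, py, pz = gx / mag, gy / mag, gz / mag
    div = np.zeros_like(mu)
    div += px - np.concatenate([np.zeros_like(px[:1]), px[:-1]], axis=0)
    div += py - np.concatenate([np.zeros_like(py[:, :1]), py[:, :-1]], axis=1)
    div += pz - np.concatenate([np.zeros_like(pz[:, :, :1]), pz[:, :, :-1]],
                               axis=2)
    return -div


def art_tv_reconstruct(projections: ProjectionSet, config: ArtTvConfig,
                       grid: Volume) -> Volume:
    """Algebraic reconstruction with total-variation regularization.

    Alternates relaxed view-wise algebraic updates (the simultaneous
    row-action form, normalized per ray and per voxel) with a few descent
    steps on the smoothed TV norm; non-negativity is enforced each sweep.
    Deterministic given the view order and configuration.
    """
    if len(projections) < 1:
        raise ValueError("need at least one view")
    geom = projections.geometry
    shape = grid.shape
    spacing, origin = grid.spacing, grid.origin
    step = _ray_step(spacing)
    mu = np.zeros(shape)
    ones_vol = np.ones(shape)
    lam = config.relaxation
    for sweep in range(config.sweeps):
        update_norm = 0.0
        for f in range(len(projections)):
            ang = projections.angles_deg[f]
            fp = project_view(mu, spacing, origin, geom, ang, step)
            row_sum = project_view(ones_vol, spacing, origin, geom, ang, step)
            resid = (projections.images[f] - fp) / np.maximum(row_sum, 1e-6)
            resid[row_sum <= 1e-6] = 0.0
            bp = backproject_view(resid, shape, spacing, origin, geom, ang,
                                  step)
            col_sum = backproject_view(np.ones_like(resid), shape, spacing,
                                       origin, geom, ang, step)
            upd = lam * bp / np.maximum(col_sum, 1e-6)
            mu += upd
            update_norm += float(np.abs(upd).max())
        np.clip(mu, 0.0, None, out=mu)
        tv_step = config.tv_step_scale * update_norm / max(len(projections), 1)
        for _ in range(config.tv_steps):
            g = _tv_gradient(mu)
            gmax = np.abs(g).max()
            if gmax > 0:
                mu -= tv_step * g / gmax
        np.clip(mu, 0.0, None, out=mu)
        if config.tol > 0 and update_norm / max(len(projections), 1) < config.tol:
            break
    return Volume(mu, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# conventional PCA baseline
# ---------------------------------------------------------------------------

def pca_cv_fit(projections: ProjectionSet, model: MotionModel, mu: Volume,
               max_iter=60, warm_start=True, w_bound=100.0):
    """Per-projection nonlinear conjugate-gradient fit of the PCA weights.

    For each frame the 9-vector w minimizes
    ``|| A mu(x + compose(w)) - P_t ||^2`` (Polak-Ribiere CG, analytic
    gradient through the warp and projector); each frame warm-starts from
    the previous one.  Frames where the line search fails fall back to the
    previous frame's weights and are flagged.

    Returns ``(WeightTrack, dvfs, flags)``.
    """
    shape = mu.shape
    spacing, origin = mu.spacing, mu.origin
    model = _prepare_model(model, shape, spacing, origin)
    geom = projections.geometry
    step = _ray_step(spacing)
    sigma = np.ascontiguousarray(mu.data, dtype=np.float64)
    base_idx = (_grid_points_mm(shape, spacing, origin) - origin) / spacing
    n_comp = model.n_components
    comps_flat = model.components.reshape(3, n_comp, -1)
    pc0_flat = model.pc0.reshape(-1, 3)

    def loss_grad(w9, f):
        w = w9.reshape(3, n_comp)
        dvf = pc0_flat.copy()
        for d in range(3):
            dvf[:, d] += w[d] @ comps_flat[d]
        pts = base_idx + dvf / spacing
        warped = trilinear_gather(sigma, pts).reshape(shape)
        drr = project_view(warped, spacing, origin, geom,
                           projections.angles_deg[f], step)
        resid = drr - projections.images[f]
        loss = float(np.sum(resid ** 2))
        g_warped = backproject_view(2.0 * resid, shape, spacing, origin, geom,
                                    projections.angles_deg[f], step)
        _, d_dvf = warp_backward(sigma, spacing, pts, g_warped.ravel())
        g = np.empty((3, n_comp))
        for d in range(3):
            g[d] = comps_flat[d] @ d_dvf[:, d]
        return loss, g.ravel()

    n = len(projections)
    weights = np.zeros((n, 3 * n_comp))
    flags = np.zeros(n, dtype=bool)
    w_prev = np.zeros(3 * n_comp)
    for f in range(n):
        x0 = w_prev if warm_start else np.zeros(3 * n_comp)
        res = optimize.minimize(loss_grad, x0, args=(f,), jac=True,
                                method="CG",
                                options={"maxiter": max_iter, "gtol": 1e-10})
        w = res.x
        if not np.all(np.isfinite(w)):
            w = w_prev.copy()
            flags[f] = True
        w = np.clip(w, -w_bound, w_bound)
        weights[f] = w
        w_prev = w
    track = WeightTrack(projections.times_s.copy(), weights)
    dvfs = [compose_dvf(model, weights[f]) for f in range(n)]
    return track, dvfs, flags


# ---------------------------------------------------------------------------
# polynomial-temporal INR baseline
# ---------------------------------------------------------------------------

@dataclass
class PolyMotionConfig:
    order: int = 3                # polynomial order p >= 1
    iters: int = 1500
    init_iters: int = 300         # spatial-INR pre-fit to the blurred FDK
    lr: float = 0.002
    batch_frames: int = 8
    opt_shape: tuple = (64, 64, 64)
    opt_spacing: float = 6.0
    preset: dict = field(default_factory=lambda: dict(SCALED_PRESET))
    seed: int = 0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("polynomial order must be >= 1")


def inr_poly_fit(projections: ProjectionSet, config: PolyMotionConfig):
    """Joint fit of a spatial INR and per-voxel polynomial motion fields.

    The displacement model is ``D(x, t) = sum_{k=1..p} t^k M_k(x)`` with
    dense coefficient grids M_k (mm); there is no motion prior, so each
    voxel's trajectory is a free polynomial of normalized time.

    Returns ``(spatial INR, M (p, nx, ny, nz, 3), loss trace)``.
    """
    shape = tuple(int(s) for s in config.opt_shape)
    spacing = np.array([config.opt_spacing] * 3, dtype=np.float64)
    origin = centered_grid(shape, spacing)
    geom = projections.geometry
    step = _ray_step(spacing)
    half = np.asarray(shape) * spacing / 2.0
    spatial = SpatialINR(np.zeros(3), half, preset=config.preset,
                         seed=config.seed)
    pts_mm = _grid_points_mm(shape, spacing, origin)
    enc_grid = spatial.encode_points(pts_mm)
    base_idx = (pts_mm - origin) / spacing
    rng = np.random.default_rng(config.seed + 7)
    t_raw = projections.times_s
    t_norm = (t_raw - t_raw.min()) / max(np.ptp(t_raw), 1e-12)

    # init: fit the (motion-blurred) all-frame FDK volume
    grid_vol = make_volume(np.zeros(shape, dtype=np.float32), spacing, origin)
    fdk = fdk_reconstruct(projections, grid_vol)
    target = fdk.data.ravel().astype(np.float32)
    opt = Adam(spatial.mlp.params(), lr=config.lr)
    for _ in range(config.init_iters):
        vals, cache = spatial.eval_encoded(enc_grid, want_cache=True)
        resid = vals - target
        grads = spatial.backward(cache, 2.0 * resid / len(target))
        opt.step(spatial.mlp.params(), grads)

    p = config.order
    M = np.zeros((p, *shape, 3))
    m_flat = M.reshape(p, -1, 3)
    opt_s = Adam(spatial.mlp.params(), lr=config.lr)
    opt_m = Adam([M], lr=config.lr)
    trace = np.empty(config.iters)
    n_frames = len(projections)
    for it in range(config.iters):
        sel = rng.choice(n_frames, size=min(config.batch_frames, n_frames),
                         replace=False)
        vals, cache_s = spatial.eval_encoded(enc_grid, want_cache=True)
        sigma = vals.reshape(shape).astype(np.float64)
        d_sigma = np.zeros(shape)
        d_m = np.zeros_like(m_flat)
        loss = 0.0
        for f in sel:
            tp = np.array([t_norm[f] ** (k + 1) for k in range(p)])
            dvf = np.tensordot(tp, m_flat, axes=(0, 0))
            pts = base_idx + dvf / spacing
            warped = trilinear_gather(sigma, pts).reshape(shape)
            drr = project_view(warped, spacing, origin, geom,
                               projections.angles_deg[f], step)
            resid = drr - projections.images[f]
            loss += float(np.sum(resid ** 2))
            g_warped = backproject_view(2.0 * resid, shape, spacing, origin,
                                        geom, projections.angles_deg[f], step)
            dv, d_dvf = warp_backward(sigma, spacing, pts, g_warped.ravel())
            d_sigma += dv
            for k in range(p):
                d_m[k] += tp[k] * d_dvf
        trace[it] = loss / len(sel)
        if not np.isfinite(trace[it]):
            raise FloatingPointError(f"loss diverged at iteration {it}")
        grads_s = spatial.backward(cache_s, d_sigma.ravel() / len(sel))
        opt_s.step(spatial.mlp.params(), grads_s)
        opt_m.step([M], [d_m.reshape(M.shape) / len(sel)])
    return spatial, M, trace
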