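"""End-to-end scenario runner tying phantom, scan, model, and methods together.

The pipeline mirrors the study protocol: simulate the ground-truth dynamic
sequence and its cone-beam scan, build the PCA motion model from the prior
4D set, reconstruct with the requested method, and score the result against
the ground truth on a common evaluation grid.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as stio
from .config import ExperimentConfig, derive_seed, save_config
from .geometry import (ProjectionSet, ScanGeometry, add_poisson_noise,
                       forward_project, gantry_angles)
from .metrics import (EvaluationReport, evaluate_sequence, propagate_mask,
                      threshold_segment)
from .motion import MotionModel, build_pca_model, compose_dvf, register_phases
from .phantom import (AnatomyParams, ATTENUATION, MotionBasis,
                      build_reference_anatomy, default_motion_basis,
                      generate_dynamic_sequence, generate_prior_4dct,
                      onboard_params)
from .recon import (ArtTvConfig, PolyMotionConfig, StinrConfig,
                    art_tv_reconstruct, extract_ee_projections, inr_poly_fit,
                    pca_cv_fit, stinr_fit, stinr_infer)
from .volume import Volume, centered_grid, make_volume, resample_to_grid
from .warp import trilinear_gather

__all__ = ["SimulatedScan", "simulate_scenario", "build_motion_model_for",
           "reconstruct_and_evaluate", "run_experiment"]

# tumor segmentation threshold: midpoint of the lung and tumor attenuation
# presets, applied to reconstructed reference volumes
TUMOR_TAU = 0.5 * (ATTENUATION["lung"] + ATTENUATION["tumor"])


@dataclass
class SimulatedScan:
    config: ExperimentConfig
    params: AnatomyParams          # prior anatomy
    basis: MotionBasis
    ref: Volume                    # onboard reference (sim grid)
    frames: list                   # GroundTruthFrame per projection
    track: object                  # BreathingTrack
    projections: ProjectionSet


def scan_geometry(cfg: ExperimentConfig) -> ScanGeometry:
    return ScanGeometry(sid=cfg.sid, sdd=cfg.sdd, det_shape=cfg.det_shape,
                        pixel_pitch=cfg.pixel_pitch,
                        rotation_speed=cfg.rotation_speed,
                        frame_rate=cfg.frame_rate)


def anatomy_params(cfg: ExperimentConfig) -> AnatomyParams:
    return AnatomyParams(grid_shape=cfg.sim_shape, spacing=cfg.sim_spacing,
                         tumor_radius=cfg.tumor_radius_mm)


def simulate_scenario(cfg: ExperimentConfig) -> SimulatedScan:
    """Ground-truth dynamic sequence plus its simulated cone-beam scan."""
    params = anatomy_params(cfg)
    basis = default_motion_basis(params)
    ref, frames, track = generate_dynamic_sequence(
        cfg.scenario, params, basis, n_frames=cfg.n_frames,
        fps=cfg.frame_rate, amplitude=cfg.amplitude_mm,
        seed=derive_seed(cfg.seed, "breathing"))
    geom = scan_geometry(cfg)
    angles = gantry_angles(cfg.n_frames, cfg.frame_rate, cfg.rotation_speed)
    images = np.empty((cfg.n_frames, *geom.det_shape))
    for i, fr in enumerate(frames):
        images[i] = forward_project(fr.volume, geom, [angles[i]]).images[0]
    projections = ProjectionSet(images, angles, track.times,
                                np.arange(1, cfg.n_frames + 1), geom)
    if cfg.noise_i0 > 0:
        projections = add_poisson_noise(projections, cfg.noise_i0,
                                        seed=derive_seed(cfg.seed, "noise"))
    return SimulatedScan(cfg, params, basis, ref, frames, track, projections)


def build_motion_model_for(cfg: ExperimentConfig, scan: SimulatedScan,
                           shape=None, spacing=None) -> MotionModel:
    """PCA motion model from the prior 4D set, on the requested grid.

    In bypass mode the prior inter-phase DVFs are the phantom's analytic
    ground truth evaluated directly on the target grid; in demons mode the
    prior phases are registered on the simulation grid (the model is
    resampled downstream as needed).
    """
    if shape is None:
        shape = cfg.opt_shape
    shape = tuple(int(s) for s in shape)
    if spacing is None:
        spacing = cfg.opt_spacing
    spacing3 = np.broadcast_to(np.asarray(spacing, float), (3,)).copy()
    origin = centered_grid(shape, spacing3)
    if cfg.registration_mode == "bypass":
        fields = scan.basis.evaluate(shape, spacing3, origin)
        _, _, _, prior_coeffs = generate_prior_4dct(
            scan.params, scan.basis, amplitude=cfg.amplitude_mm)
        gt_dvfs = [np.tensordot(prior_coeffs[p, : scan.basis.k], fields,
                                axes=(0, 0))
                   for p in range(1, prior_coeffs.shape[0])]
        dvfs = register_phases(None, None, mode="bypass", gt_dvfs=gt_dvfs,
                               noise_sigma=cfg.registration_noise_mm,
                               seed=derive_seed(cfg.seed, "regnoise"))
    else:
        ref, phases, _, _ = generate_prior_4dct(
            scan.params, scan.basis, amplitude=cfg.amplitude_mm)
        dvfs = register_phases(ref, phases[1:], mode="demons")
        model = build_pca_model(dvfs, n=cfg.n_components,
                                spacing=ref.spacing, origin=ref.origin)
        return model.resampled(shape, spacing3, origin)
    return build_pca_model(dvfs, n=cfg.n_components, spacing=spacing3,
                           origin=origin)


# ---------------------------------------------------------------------------
# evaluation plumbing
# ---------------------------------------------------------------------------

def _eval_grid(cfg: ExperimentConfig):
    shape = cfg.eval_shape or cfg.sim_shape
    extent = np.asarray(cfg.sim_shape) * cfg.sim_spacing
    spacing = extent / np.asarray(shape)
    return tuple(int(s) for s in shape), spacing, centered_grid(shape, spacing)


def _gt_at_eval_grid(cfg: ExperimentConfig, scan: SimulatedScan):
    """Ground-truth volumes and tumor masks on the evaluation grid."""
    shape, spacing, origin = _eval_grid(cfg)
    if shape == tuple(scan.ref.shape):
        vols = [fr.volume.data for fr in scan.frames]
        masks = [fr.tumor_mask for fr in scan.frames]
        ref_mask = scan.ref.masks["tumor"]
    else:
        ob = onboard_params(cfg.scenario, scan.params)
        from dataclasses import replace
        ob = replace(ob, grid_shape=shape, spacing=float(spacing[0]))
        ref = build_reference_anatomy(ob)
        fields = scan.basis.evaluate(shape, spacing, origin)
        from .phantom import render_frame
        vols, masks = [], []
        for i in range(len(scan.frames)):
            fr = render_frame(ref, fields, scan.track.coeffs[i, : scan.basis.k])
            vols.append(fr.volume.data)
            masks.append(fr.tumor_mask)
        ref_mask = ref.masks["tumor"]
    return vols, masks, ref_mask


def _segment_reference(ref_data, gt_ref_mask):
    """Tumor mask of a reconstructed reference: threshold + seeded component.

    The reference is lightly smoothed (1 voxel) first: iterative
    reconstructions carry speckle that would otherwise bridge the tumor to
    neighboring above-threshold structures.

    Degraded reconstructions (e.g., a limited-angle algebraic reference
    under non-periodic motion) may have no component above the nominal
    threshold: the segmentation then falls back to a local half-max
    threshold, and finally to the brightest in-seed decile, so that a
    failed method is scored as a gross miss instead of crashing the
    evaluation.
    """
    from scipy import ndimage
    seed = ndimage.binary_dilation(gt_ref_mask, iterations=3)
    smoothed = ndimage.gaussian_filter(np.asarray(ref_data, dtype=np.float64),
                                       1.0)
    try:
        return threshold_segment(smoothed, TUMOR_TAU, seed_region=seed)
    except ValueError:
        pass
    shell = ndimage.binary_dilation(seed, iterations=3) & ~seed
    background = float(np.median(smoothed[shell])) if shell.any() else 0.0
    peak = float(smoothed[seed].max())
    if peak > background:
        try:
            return threshold_segment(smoothed, 0.5 * (background + peak),
                                     seed_region=seed)
        except ValueError:
            pass
    top = np.quantile(smoothed[seed], 0.9)
    mask = seed & (smoothed >= top)
    if not mask.any():
        mask = gt_ref_mask.copy()
    return mask


def _propagate_robust(ref_mask, dvf, spacing):
    """Propagated mask, with fallbacks when the solved motion is so wrong
    that the binarized warp empties: a failed motion estimate must still be
    scored (as a gross miss), not crash the evaluation."""
    mask = propagate_mask(ref_mask, dvf, spacing)
    if mask.any():
        return mask
    ind = make_volume(ref_mask.astype(np.float32),
                      np.broadcast_to(np.asarray(spacing, float), (3,)))
    soft = trilinear_gather(
        np.ascontiguousarray(ind.data, dtype=np.float64),
        _base_idx(ind.shape, ind.spacing, ind.origin)
        + np.asarray(dvf, dtype=np.float64).reshape(-1, 3) / ind.spacing
    ).reshape(ind.shape)
    mask = soft >= 0.05
    return mask if mask.any() else ref_mask


def _score(cfg, scan, recon_vols, recon_ref_data, dvfs, spacing):
    gt_vols, gt_masks, gt_ref_mask = _gt_at_eval_grid(cfg, scan)
    ref_mask = _segment_reference(recon_ref_data, gt_ref_mask)
    masks = [_propagate_robust(ref_mask, d, spacing) for d in dvfs]
    return evaluate_sequence(recon_vols, masks, gt_vols, gt_masks, spacing)


def _resample_model(model, shape, spacing, origin):
    if model.grid_shape == shape and np.allclose(model.spacing, spacing):
        return model
    return model.resampled(shape, spacing, origin)


def reconstruct_and_evaluate(cfg: ExperimentConfig, scan: SimulatedScan,
                             model: MotionModel):
    """Run the configured method and score it; returns (artifacts, report)."""
    shape, spacing, origin = _eval_grid(cfg)
    geom = scan.projections.geometry
    out = {}
    if cfg.method == "stinr":
        sc = StinrConfig(stage1_iters=cfg.stage_iters[0],
                         stage2_iters=cfg.stage_iters[1],
                         stage3_iters=cfg.stage_iters[2], lr=cfg.lr,
                         batch_frames=cfg.batch_frames,
                         opt_shape=cfg.opt_shape, opt_spacing=cfg.opt_spacing,
                         seed=derive_seed(cfg.seed, "stinr"),
                         ee_fraction=cfg.ee_fraction)
        result = stinr_fit(scan.projections, model, sc,
                           signal=scan.track.signal)
        vols, track, ref, dvfs = stinr_infer(result, scan.track.times, shape,
                                             spacing)
        out.update(result=result, weight_track=track, reference=ref,
                   loss_trace=result.loss_trace)
        report = _score(cfg, scan, [v.data for v in vols], ref.data, dvfs,
                        spacing)
    elif cfg.method == "pcacv":
        ee, _ = extract_ee_projections(scan.projections, scan.track.signal,
                                       cfg.ee_fraction)
        grid = make_volume(np.zeros(cfg.opt_shape, dtype=np.float32),
                           cfg.opt_spacing)
        mu = art_tv_reconstruct(ee, ArtTvConfig(), grid)
        model_opt = _resample_model(model, tuple(cfg.opt_shape),
                                    np.asarray([cfg.opt_spacing] * 3),
                                    grid.origin)
        track, _, flags = pca_cv_fit(scan.projections, model_opt, mu)
        mu_eval = resample_to_grid(mu, shape, spacing, origin)
        model_eval = _resample_model(model, shape, spacing, origin)
        dvfs = [compose_dvf(model_eval, w) for w in track.weights]
        base = _base_idx(shape, spacing, origin)
        vols = [_warp_data(mu_eval.data, base, d, spacing) for d in dvfs]
        out.update(reference=mu_eval, weight_track=track, flags=flags)
        report = _score(cfg, scan, vols, mu_eval.data, dvfs, spacing)
    elif cfg.method == "inrpoly":
        pc = PolyMotionConfig(opt_shape=cfg.opt_shape,
                              opt_spacing=cfg.opt_spacing, lr=cfg.lr,
                              batch_frames=cfg.batch_frames,
                              iters=cfg.stage_iters[2],
                              init_iters=cfg.stage_iters[0],
                              seed=derive_seed(cfg.seed, "inrpoly"))
        spatial, M, trace = inr_poly_fit(scan.projections, pc)
        sigma = np.clip(spatial.eval_grid(shape, spacing, origin), 0, None)
        M_eval = _resample_poly_fields(M, cfg, shape, spacing, origin)
        t = scan.track.times
        t_norm = (t - t.min()) / max(np.ptp(t), 1e-12)
        base = _base_idx(shape, spacing, origin)
        vols, dvfs = [], []
        for i in range(len(t)):
            tp = np.array([t_norm[i] ** (k + 1) for k in range(pc.order)])
            dvf = np.tensordot(tp, M_eval, axes=(0, 0))
            dvfs.append(dvf)
            vols.append(_warp_data(sigma, base, dvf, spacing))
        out.update(reference=make_volume(sigma.astype(np.float32), spacing),
                   motion_fields=M, loss_trace={"joint": trace})
        report = _score(cfg, scan, vols, sigma, dvfs, spacing)
    elif cfg.method == "fdk":
        from .geometry import fdk_reconstruct
        grid = make_volume(np.zeros(shape, dtype=np.float32), spacing, origin)
        vol = fdk_reconstruct(scan.projections, grid)
        gt_vols, gt_masks, gt_ref_mask = _gt_at_eval_grid(cfg, scan)
        ref_mask = _segment_reference(vol.data, gt_ref_mask)
        zero = np.zeros((*shape, 3))
        masks = [ref_mask] * len(gt_vols)
        report = evaluate_sequence([vol.data] * len(gt_vols), masks, gt_vols,
                                   gt_masks, spacing)
        out.update(reference=vol)
    else:  # pragma: no cover - config validation rejects other methods
        raise ValueError(cfg.method)
    return out, report


def _base_idx(shape, spacing, origin):
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    return (pts - origin) / spacing


def _warp_data(data, base_idx, dvf, spacing):
    pts = base_idx + dvf.reshape(-1, 3) / spacing
    return trilinear_gather(np.ascontiguousarray(data, dtype=np.float64),
                            pts).reshape(data.shape)


def _resample_poly_fields(M, cfg, shape, spacing, origin):
    src_spacing = np.asarray([cfg.opt_spacing] * 3)
    if tuple(M.shape[1:4]) == shape and np.allclose(src_spacing, spacing):
        return M.reshape(M.shape[0], -1, 3)
    out = np.empty((M.shape[0], int(np.prod(shape)), 3))
    for k in range(M.shape[0]):
        for d in range(3):
            v = make_volume(M[k, ..., d], src_spacing)
            out[k, :, d] = resample_to_grid(v, shape, spacing, origin).data.ravel()
    return out


# ---------------------------------------------------------------------------
# artifact-directory runner
# ---------------------------------------------------------------------------

def _checksum(path: Path):
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig, outdir=None):
    """Full pipeline with on-disk artifacts and a reproducibility manifest.

    Writes the phantom reference, projections, motion model, reconstruction
    outputs, per-frame metric CSV, aggregate JSON, and a manifest recording
    the config hash, derived seeds, and file checksums.  Rerunning with the
    same config reproduces the report bit-identically.
    """
    outdir = Path(outdir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash, "seed": cfg.seed,
                "derived_seeds": {k: derive_seed(cfg.seed, k)
                                  for k in ("breathing", "noise", "stinr",
                                            "inrpoly", "regnoise")},
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "files": {}, "status": "running"}
    save_config(outdir / "config.yaml", cfg)
    try:
        scan = simulate_scenario(cfg)
        stio.save_volume_nifti(outdir / "reference.nii.gz", scan.ref)
        stio.save_volume_nifti(
            outdir / "reference_tumor_mask.nii.gz",
            Volume(scan.ref.masks["tumor"].astype(np.uint8),
                   scan.ref.spacing, scan.ref.origin))
        stio.save_projections(outdir / "projections.h5", scan.projections)
        k = scan.track.coeffs.shape[1]
        stio.save_track_csv(outdir / "breathing_track.csv", scan.track.times,
                            np.column_stack([scan.track.coeffs,
                                             scan.track.signal]),
                            [f"c{i + 1}" for i in range(k)] + ["signal_mm"])
        model = build_motion_model_for(cfg, scan)
        stio.save_motion_model(outdir / "motion_model.h5", model)
        artifacts, report = reconstruct_and_evaluate(cfg, scan, model)
        if "result" in artifacts:
            stio.save_checkpoint(outdir / "checkpoint.h5",
                                 artifacts["result"].spatial,
                                 artifacts["result"].temporal)
        if "weight_track" in artifacts:
            wt = artifacts["weight_track"]
            stio.save_track_csv(outdir / "weights.csv", wt.times, wt.weights,
                                [f"w{d}{n}" for d in "xyz" for n in "123"])
        if "loss_trace" in artifacts:
            for k2, v in artifacts["loss_trace"].items():
                np.savetxt(outdir / f"loss_{k2}.csv", v, delimiter=",")
        np.savetxt(outdir / "metrics_per_frame.csv",
                   report.per_frame_table(), delimiter=",",
                   header="frame,re,dice,come_mm", comments="")
        (outdir / "report.json").write_text(
            json.dumps(report.summary, indent=2, sort_keys=True))
        _plot_trajectory(outdir, scan, report)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _checksum(p)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return outdir, report


def _plot_trajectory(outdir, scan, report: EvaluationReport):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(scan.track.times, report.traj_gt, label="ground truth")
    ax.plot(scan.track.times, report.traj_recon, "--", label="reconstructed")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("tumor SI centroid [mm]")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "trajectory_si.png", dpi=110)
    plt.close(fig)
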