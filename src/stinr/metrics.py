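"""Evaluation metrics for dynamic CBCT reconstructions.

Relative error against ground-truth attenuation, DICE overlap of tumor
masks, and the tumor center-of-mass error (COME, mm), plus tumor
segmentation/propagation and per-scenario report aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume, make_volume
from .warp import warp_volume

__all__ = [
    "relative_error", "dice_coefficient", "center_of_mass_error",
    "threshold_segment", "propagate_mask", "evaluate_sequence",
    "EvaluationReport",
]


def relative_error(mu_recon, mu_gt):
    """RE = sqrt(sum((recon - gt)^2) / sum(gt^2))."""
    mu_recon = np.asarray(mu_recon, dtype=np.float64)
    mu_gt = np.asarray(mu_gt, dtype=np.float64)
    denom = np.sum(mu_gt ** 2)
    if denom == 0:
        raise ValueError("ground truth is identically zero")
    return float(np.sqrt(np.sum((mu_recon - mu_gt) ** 2) / denom))


def dice_coefficient(mask_recon, mask_gt):
    """DICE = 2 |A & B| / (|A| + |B|); symmetric, in [0, 1]."""
    a = np.asarray(mask_recon, dtype=bool)
    b = np.asarray(mask_gt, dtype=bool)
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / (na + nb))


def center_of_mass_error(mask_recon, mask_gt, spacing):
    """Euclidean distance (mm) between mask centroids."""
    a = np.asarray(mask_recon, dtype=bool)
    b = np.asarray(mask_gt, dtype=bool)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty mask")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    ca = np.asarray(ndimage.center_of_mass(a)) * spacing
    cb = np.asarray(ndimage.center_of_mass(b)) * spacing
    return float(np.linalg.norm(ca - cb))


def threshold_segment(volume, tau, seed_region=None):
    """Connected component above ``tau`` selected via ``seed_region``.

    Without a seed the largest component is returned.  With a seed, the
    component overlapping the seed most is chosen: a seed derived from a
    dilated tumor neighborhood may graze a neighboring organ, and ranking
    by seed overlap (rather than raw size) keeps the selection on the
    target.  Raises if the selection is empty.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    above = data > tau
    if not above.any():
        raise ValueError("no voxels above threshold")
    labels, n = ndimage.label(above)
    if seed_region is not None:
        seed = np.asarray(seed_region, dtype=bool)
        candidates = np.unique(labels[seed & above])
        candidates = candidates[candidates > 0]
        if len(candidates) == 0:
            raise ValueError("no component intersects the seed region")
        overlap = ndimage.sum_labels(seed.astype(np.float64), labels,
                                     candidates)
        return labels == candidates[int(np.argmax(overlap))]
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64),
                               labels, np.arange(1, n + 1))
    return labels == 1 + int(np.argmax(sizes))


def propagate_mask(reference_mask, dvf, spacing, origin=None):
    """Backward-warp a mask indicator by ``dvf`` (mm) and re-binarize at 0.5."""
    mask = np.asarray(reference_mask)
    dvf = np.asarray(dvf, dtype=np.float64)
    if dvf.shape != (*mask.shape, 3):
        raise ValueError("dvf grid does not match the mask")
    ind = make_volume(mask.astype(np.float32), spacing, origin)
    return warp_volume(ind, dvf).data >= 0.5


@dataclass
class EvaluationReport:
    """Per-frame metrics, scenario aggregates, and SI centroid trajectories."""

    re: np.ndarray          # per-frame relative error
    dice: np.ndarray        # per-frame DICE
    come: np.ndarray        # per-frame center-of-mass error, mm
    traj_recon: np.ndarray  # tracked SI tumor centroid, mm
    traj_gt: np.ndarray
    spacing: np.ndarray

    @property
    def summary(self):
        return {
            "re_mean": float(np.mean(self.re)),
            "re_sd": float(np.std(self.re)),
            "dice_mean": float(np.mean(self.dice)),
            "dice_sd": float(np.std(self.dice)),
            "come_mean_mm": float(np.mean(self.come)),
            "come_sd_mm": float(np.std(self.come)),
            "n_frames": int(len(self.re)),
        }

    def per_frame_table(self):
        """Rows of (frame, re, dice, come_mm) for CSV export."""
        return np.column_stack([np.arange(len(self.re)), self.re,
                                self.dice, self.come])


def _si_centroid(mask, spacing):
    return float(np.asarray(ndimage.center_of_mass(mask))[2] * spacing[2])


def evaluate_sequence(recon_volumes, recon_masks, gt_volumes, gt_masks,
                      spacing) -> EvaluationReport:
    """Frame-by-frame RE / DICE / COME plus SI-trajectory extraction.

    All four sequences must have equal length; volumes may be Volume objects
    or raw arrays on a common grid.
    """
    n = len(gt_volumes)
    if not (len(recon_volumes) == len(recon_masks) == len(gt_masks) == n):
        raise ValueError("sequence lengths disagree")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    re = np.empty(n)
    dice = np.empty(n)
    come = np.empty(n)
    traj_r = np.empty(n)
    traj_g = np.empty(n)
    for i in range(n):
        mr = recon_volumes[i].data if isinstance(recon_volumes[i], Volume) \
            else np.asarray(recon_volumes[i])
        mg = gt_volumes[i].data if isinstance(gt_volumes[i], Volume) \
            else np.asarray(gt_volumes[i])
        re[i] = relative_error(mr, mg)
        dice[i] = dice_coefficient(recon_masks[i], gt_masks[i])
        come[i] = center_of_mass_error(recon_masks[i], gt_masks[i], spacing)
        traj_r[i] = _si_centroid(recon_masks[i], spacing)
        traj_g[i] = _si_centroid(gt_masks[i], spacing)
    return EvaluationReport(re, dice, come, traj_r, traj_g, spacing.copy())
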