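"""PCA respiratory motion model.

From the inter-phase deformation fields of a prior 4D set (reference = the
end-expiration phase), a principal-component motion model is extracted
independently along each Cartesian direction: the mean field PC0 plus the
first n = 3 scaled principal components per direction.  Any intra-scan
deformation is then composed from a 9-vector of dimensionless weights,

    D = PC0 + sum_dim sum_n w[dim, n] * PC[dim, n].

The components are scaled by singular value / sqrt(m - 1) (one standard
deviation of the training coefficient), so a unit weight corresponds to one
SD of the training motion and downstream optimizers see O(1) variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = [
    "MotionModel", "WeightTrack", "register_phases", "build_pca_model",
    "compose_dvf", "project_dvf_to_weights",
]


@dataclass
class MotionModel:
    """Mean DVF and per-direction scaled principal motion components."""

    pc0: np.ndarray        # (nx, ny, nz, 3) mm
    components: np.ndarray  # (3 dims, n, nx, ny, nz) mm per unit weight
    scales: np.ndarray     # (3, n) singular-value scales applied
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def n_components(self):
        return self.components.shape[1]

    @property
    def grid_shape(self):
        return self.pc0.shape[:3]

    def resampled(self, shape, spacing, origin=None):
        """Trilinearly resample the model onto another grid (same space)."""
        from .volume import resample_to_grid, make_volume, centered_grid
        shape = tuple(int(s) for s in shape)
        spacing3 = np.broadcast_to(np.asarray(spacing, float), (3,)).copy()
        if origin is None:
            origin = centered_grid(shape, spacing3)
        def rs(field):
            v = make_volume(field, self.spacing, self.origin.copy())
            return resample_to_grid(v, shape, spacing3, origin).data
        pc0 = np.stack([rs(self.pc0[..., d]) for d in range(3)], axis=-1)
        comps = np.stack([
            np.stack([rs(self.components[d, n]) for n in range(self.n_components)])
            for d in range(3)])
        return MotionModel(pc0, comps, self.scales.copy(), spacing3,
                           np.asarray(origin, dtype=np.float64))


@dataclass
class WeightTrack:
    """Per-frame 9-vector of principal-component weights."""

    times: np.ndarray    # s
    weights: np.ndarray  # (T, 9) ordered (dim major, component minor)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or len(self.times) != len(self.weights):
            raise ValueError("need one weight vector per frame")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def register_phases(reference: Volume, phases, mode="demons",
                    gt_dvfs=None, noise_sigma=0.0, seed=0,
                    iterations=(40, 30, 20)):
    """Inter-phase DVFs (pull-back, EE -> phase) for each non-reference phase.

    Parameters
    ----------
    reference : Volume
        The end-expiration phase.
    phases : sequence of Volume
        The non-reference phases.
    mode : {"demons", "bypass"}
        ``demons``: multi-resolution demons registration (SimpleITK backend).
        ``bypass``: return the phantom's ground-truth DVFs, optionally with
        seeded Gaussian perturbation of ``noise_sigma`` mm, isolating the
        downstream pipeline from registration error.
    """
    if mode == "bypass":
        if gt_dvfs is None:
            raise ValueError("bypass mode requires gt_dvfs")
        rng = np.random.default_rng(seed)
        out = []
        for d in gt_dvfs:
            d = np.asarray(d, dtype=np.float64)
            if noise_sigma > 0:
                d = d + rng.normal(0.0, noise_sigma, size=d.shape)
            out.append(d)
        return out
    if mode != "demons":
        raise ValueError(f"unknown registration mode: {mode!r}")
    return [_demons_register(reference, ph, iterations) for ph in phases]


def _demons_register(reference: Volume, moving_target: Volume, iterations):
    """Demons DVF such that target(x) ~= reference(x + D(x))."""
    import SimpleITK as sitk
    if reference.shape != moving_target.shape:
        raise ValueError("phase volumes must share the reference grid")

    def to_sitk(vol):
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.data.T.astype(np.float64)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        return img

    fixed = to_sitk(moving_target)   # field is sampled on the phase grid
    moving = to_sitk(reference)
    # intensity rescale keeps demons forces comparable across phantoms
    filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    filt.SetSmoothDisplacementField(True)
    filt.SetStandardDeviations(1.5 * float(np.min(reference.spacing)))
    field = None
    for level, n_iter in zip((4, 2, 1), iterations):
        f = fixed if level == 1 else _shrink(fixed, level)
        m = moving if level == 1 else _shrink(moving, level)
        filt.SetNumberOfIterations(int(n_iter))
        if field is not None:
            field = sitk.Resample(field, f, sitk.Transform(),
                                  sitk.sitkLinear)
            field = sitk.Cast(field, sitk.sitkVectorFloat64)
            field = filt.Execute(f, m, field)
        else:
            field = filt.Execute(f, m)
    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3) with (x, y, z) vectors
    return np.ascontiguousarray(arr.transpose(2, 1, 0, 3))


def _shrink(img, factor):
    import SimpleITK as sitk
    return sitk.Shrink(sitk.SmoothingRecursiveGaussian(
        img, float(factor) / 2.0 * min(img.GetSpacing())), [factor] * 3)


def build_pca_model(dvfs, n=3, spacing=None, origin=None) -> MotionModel:
    """Per-direction PCA of the inter-phase DVFs.

    Along each Cartesian direction the flattened DVF components are
    mean-centered and decomposed by SVD; the top-``n`` right-singular
    structures become spatial components, each scaled by
    singular value / sqrt(m - 1).  Component signs follow the convention
    that the spatially-summed displacement is non-negative.
    """
    dvfs = [np.asarray(d, dtype=np.float64) for d in dvfs]
    m = len(dvfs)
    if m < n + 1:
        raise ValueError(f"need at least n+1 = {n + 1} DVFs, got {m}")
    shape = dvfs[0].shape[:3]
    pc0 = np.mean(dvfs, axis=0)
    comps = np.zeros((3, n, *shape))
    scales = np.zeros((3, n))
    for d in range(3):
        x = np.stack([f[..., d].ravel() for f in dvfs])  # (m, voxels)
        x = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        # rank guard: training motion may excite fewer than n modes along
        # a direction; numerically-null components are stored as exact
        # zeros so composition and projection stay well conditioned
        s_floor = 1e-7 * (s[0] if len(s) and s[0] > 0 else 1.0)
        for j in range(min(n, len(s))):
            if s[j] <= s_floor:
                continue
            scale = s[j] / np.sqrt(max(m - 1, 1))
            comp = vt[j].reshape(shape) * scale
            if comp.sum() < 0:
                comp = -comp
            comps[d, j] = comp
            scales[d, j] = scale
    if spacing is None:
        spacing = np.ones(3)
    if origin is None:
        from .volume import centered_grid
        origin = centered_grid(shape, np.broadcast_to(
            np.asarray(spacing, float), (3,)))
    return MotionModel(pc0, comps, scales,
                       np.broadcast_to(np.asarray(spacing, float), (3,)).copy(),
                       np.asarray(origin, dtype=np.float64))


def explained_variance(dvfs, n=3):
    """Per-direction fraction of variance captured by the top-n components."""
    dvfs = [np.asarray(d, dtype=np.float64) for d in dvfs]
    fractions = []
    for d in range(3):
        x = np.stack([f[..., d].ravel() for f in dvfs])
        x = x - x.mean(axis=0)
        s = np.linalg.svd(x, compute_uv=False)
        tot = np.sum(s ** 2)
        fractions.append(1.0 if tot == 0 else np.sum(s[:n] ** 2) / tot)
    return np.asarray(fractions)


def compose_dvf(model: MotionModel, w):
    """D = PC0 + sum w[dim, n] * PC[dim, n]; ``w`` is the flat 9-vector."""
    n = model.n_components
    w = np.asarray(w, dtype=np.float64).reshape(3, n)
    out = model.pc0.copy()
    for d in range(3):
        out[..., d] += np.tensordot(w[d], model.components[d], axes=(0, 0))
    return out


def project_dvf_to_weights(model: MotionModel, dvf):
    """Least-squares weights minimizing ||compose(w) - dvf||_2.

    The per-direction components are orthogonal before scaling, so the
    normal equations decouple into per-component projections.
    """
    dvf = np.asarray(dvf, dtype=np.float64)
    n = model.n_components
    w = np.zeros((3, n))
    resid = dvf - model.pc0
    if not np.any(model.scales > 0):
        raise ValueError("degenerate motion model: no active components")
    for d in range(3):
        for j in range(n):
            if model.scales[d, j] <= 0:
                continue  # inactive (rank-deficient) slot
            comp = model.components[d, j]
            w[d, j] = np.sum(resid[..., d] * comp) / np.sum(comp * comp)
    return w.ravel()
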