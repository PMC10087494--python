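"""Parametric dynamic-thorax phantom.

A digital thorax built from smooth implicit shapes (body, lungs, heart,
spine, and a spherical lung tumor) provides the prior 10-phase 4D volume set,
the per-projection ground-truth dynamic sequence for each motion/anatomy
scenario, and all ground-truth auxiliaries: deformation fields, tumor masks,
and the scalar breathing signal.

Motion is constructed as a low-rank field,

    D(x, t) = sum_k c_k(t) * b_k(x),

with K <= 3 smooth, SI-dominant displacement basis fields b_k that vanish at
the body shell and spine.  Because the ground-truth motion lives exactly in a
rank-K space, a principal-component motion model built from noiseless
inter-phase fields can represent the intra-scan motion exactly, which makes
parameter recovery a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import Volume, make_volume, centered_grid
from .warp import warp_volume

__all__ = [
    "AnatomyParams", "MotionBasis", "BreathingTrack", "GroundTruthFrame",
    "build_reference_anatomy", "default_motion_basis", "breathing_track",
    "render_frame", "generate_prior_4dct", "generate_dynamic_sequence",
    "SCENARIO_IDS",
]

# attenuation presets, mm^-1 (all within the CBCT display window [0, 0.05])
ATTENUATION = {
    "air": 0.0,
    "lung": 0.005,
    "soft": 0.020,
    "tumor": 0.028,
    "bone": 0.045,
}


@dataclass
class AnatomyParams:
    """Geometry (mm) and attenuation (mm^-1) of the parametric thorax."""

    grid_shape: tuple = (64, 64, 64)
    spacing: float = 3.0
    # axes: x lateral (right +), y anterior-posterior, z superior-inferior
    body_axes: tuple = (85.0, 62.0, 92.0)
    lung_r_center: tuple = (40.0, 0.0, 8.0)
    lung_r_axes: tuple = (33.0, 42.0, 62.0)
    lung_l_center: tuple = (-40.0, 0.0, 8.0)
    lung_l_axes: tuple = (30.0, 40.0, 60.0)
    heart_center: tuple = (-14.0, 12.0, -12.0)
    heart_axes: tuple = (26.0, 26.0, 32.0)
    spine_center_y: float = -44.0
    spine_radius: float = 12.0
    # seated in the lower lobe of the right lung with >= 2 coarse-grid
    # voxels of lung clearance around the sphere, so the tumor remains a
    # connected component distinct from the chest wall at every supported
    # reconstruction resolution
    tumor_center: tuple = (40.0, 0.0, -20.0)
    tumor_radius: float = 15.0
    edge_mm: float = 3.0            # smooth partial-volume edge width
    attenuation: dict = field(default_factory=lambda: dict(ATTENUATION))

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape) or self.spacing <= 0:
            raise ValueError("grid and spacing must be positive")
        if any(a < 0 for a in self.attenuation.values()):
            raise ValueError("attenuations must be non-negative")
        if any(a > 0.05 for a in self.attenuation.values()):
            raise ValueError("attenuations must lie within [0, 0.05] mm^-1")
        self._check_tumor_in_lung()

    def _check_tumor_in_lung(self):
        """Tumor sphere must lie strictly inside one lung."""
        c = np.asarray(self.tumor_center)
        r = self.tumor_radius
        # sample the tumor surface and test the lung implicit
        th = np.linspace(0, np.pi, 9)
        ph = np.linspace(0, 2 * np.pi, 17)
        tt, pp = np.meshgrid(th, ph)
        pts = c + r * np.stack([np.sin(tt) * np.cos(pp),
                                np.sin(tt) * np.sin(pp),
                                np.cos(tt)], axis=-1).reshape(-1, 3)
        for lc, la in ((self.lung_r_center, self.lung_r_axes),
                       (self.lung_l_center, self.lung_l_axes)):
            rho = np.sqrt((((pts - np.asarray(lc)) / np.asarray(la)) ** 2)
                          .sum(axis=1))
            if np.all(rho < 1.0):
                return
        raise ValueError("tumor must lie strictly inside a lung")


def _smoothstep(d, edge):
    """0 -> 1 occupancy as signed distance proxy d goes negative; C1 smooth."""
    x = np.clip(0.5 - d / edge, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ellipsoid_occ(pts, center, axes, edge):
    rho = np.sqrt((((pts - np.asarray(center)) / np.asarray(axes)) ** 2)
                  .sum(axis=-1))
    # convert the normalized radius to an approximate mm distance
    scale = float(np.min(axes))
    return _smoothstep((rho - 1.0) * scale, edge)


def _grid_points(params: AnatomyParams):
    shape = tuple(int(s) for s in params.grid_shape)
    spacing = np.array([params.spacing] * 3)
    origin = centered_grid(shape, spacing)
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack(g, axis=-1), spacing, origin


def build_reference_anatomy(params: AnatomyParams) -> Volume:
    """Rasterize the thorax: attenuation volume + per-tissue boolean masks.

    Deterministic given ``params``.  Organ edges are smoothed over
    ``edge_mm`` so the same implicit anatomy rasterizes consistently at any
    grid resolution; masks threshold occupancy at 0.5.
    """
    pts, spacing, origin = _grid_points(params)
    att = params.attenuation
    occ_body = _ellipsoid_occ(pts, (0, 0, 0), params.body_axes, params.edge_mm)
    occ_lr = _ellipsoid_occ(pts, params.lung_r_center, params.lung_r_axes,
                            params.edge_mm)
    occ_ll = _ellipsoid_occ(pts, params.lung_l_center, params.lung_l_axes,
                            params.edge_mm)
    occ_lung = np.maximum(occ_lr, occ_ll)
    occ_heart = _ellipsoid_occ(pts, params.heart_center, params.heart_axes,
                               params.edge_mm)
    d_spine = np.sqrt(pts[..., 0] ** 2
                      + (pts[..., 1] - params.spine_center_y) ** 2) \
        - params.spine_radius
    occ_spine = _smoothstep(d_spine, params.edge_mm) * occ_body
    d_tum = np.linalg.norm(pts - np.asarray(params.tumor_center), axis=-1) \
        - params.tumor_radius
    occ_tumor = _smoothstep(d_tum, params.edge_mm)

    mu = np.zeros(pts.shape[:3])
    mu = mu + occ_body * att["soft"]
    mu = mu + occ_lung * (att["lung"] - att["soft"])
    mu = mu + occ_heart * np.maximum(occ_lung, 0) * (att["soft"] - att["lung"])
    mu = mu + occ_spine * (att["bone"] - att["soft"])
    mu = mu + occ_tumor * (att["tumor"] - att["lung"])
    mu = np.clip(mu, 0.0, None)

    masks = {
        "body": occ_body > 0.5,
        "lung": (occ_lung > 0.5) & (occ_tumor <= 0.5) & (occ_heart <= 0.5),
        "heart": occ_heart > 0.5,
        "spine": occ_spine > 0.5,
        "tumor": occ_tumor > 0.5,
    }
    return Volume(mu.astype(np.float32), spacing, origin, masks)


# ---------------------------------------------------------------------------
# motion basis
# ---------------------------------------------------------------------------

@dataclass
class MotionBasis:
    """K smooth displacement basis fields (mm per unit coefficient).

    The fields are analytic functions of world position, so they can be
    evaluated consistently on any grid.  ``evaluate`` returns an array of
    shape (K, nx, ny, nz, 3).
    """

    params: AnatomyParams
    k: int = 3

    def _weight(self, pts):
        """Deformable-region weight: 1 in the thorax core, 0 at shell/spine."""
        p = self.params
        core_axes = np.asarray(p.body_axes) - 12.0
        occ_core = _ellipsoid_occ(pts, (0, 0, 0), core_axes, 14.0)
        d_spine = np.sqrt(pts[..., 0] ** 2
                          + (pts[..., 1] - p.spine_center_y) ** 2) \
            - (p.spine_radius + 6.0)
        not_spine = 1.0 - _smoothstep(d_spine, 10.0)
        return occ_core * not_spine

    def evaluate_points(self, pts):
        pts = np.asarray(pts, dtype=np.float64)
        w = self._weight(pts)
        z = pts[..., 2]
        out = np.zeros((self.k, *pts.shape[:-1], 3))
        # b1: diaphragm-driven SI displacement, strongest inferiorly, with a
        # small anterior chest-rise component
        a1 = 0.5 * (1.0 - np.tanh((z - 15.0) / 45.0))
        out[0, ..., 2] = -a1 * w
        out[0, ..., 1] = 0.18 * a1 * w
        if self.k >= 2:
            # b2: AP chest-wall expansion, strongest superiorly
            a2 = 0.5 * (1.0 + np.tanh((z - 0.0) / 45.0))
            out[1, ..., 1] = 0.8 * a2 * w
            out[1, ..., 2] = -0.15 * a2 * w
        if self.k >= 3:
            # b3: mid-thorax SI mode with a lateral component (hysteresis-like
            # second-order motion direction)
            a3 = np.exp(-(z / 45.0) ** 2)
            out[2, ..., 2] = -0.6 * a3 * w
            out[2, ..., 0] = 0.3 * a3 * w
        return out

    def evaluate(self, shape, spacing, origin=None):
        shape = tuple(int(s) for s in shape)
        spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
        if origin is None:
            origin = centered_grid(shape, spacing)
        axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return self.evaluate_points(np.stack(g, axis=-1))


def default_motion_basis(params: AnatomyParams, k=3) -> MotionBasis:
    return MotionBasis(params, k)


# ---------------------------------------------------------------------------
# breathing tracks / scenarios
# ---------------------------------------------------------------------------

@dataclass
class BreathingTrack:
    """Per-frame motion coefficient tracks and the scalar surrogate signal."""

    times: np.ndarray      # s
    coeffs: np.ndarray     # (T, K), dimensionless multipliers of b_k (mm)
    scenario: str
    signal: np.ndarray     # SI diaphragm-displacement surrogate, mm

    def __post_init__(self):
        if len(self.times) != len(self.coeffs) or len(self.times) != len(self.signal):
            raise ValueError("track lengths disagree")


# Scenario closed forms.  The published study describes the scenarios only
# qualitatively; the magnitudes below are this package's documented choices.
# The base cycle is a 5 s sin^2 breathing curve starting at end-expiration.
BASE_AMPLITUDE = 10.0   # mm peak SI coefficient
BASE_PERIOD = 5.0       # s
SCENARIO_IDS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8",
                "S1-P", "S2-P", "S3-P", "S4-P", "static")

# patient-study motion analogs map onto the same closed forms
_ALIASES = {"S1-P": "S1", "S2-P": "S4", "S3-P": "S5", "S4-P": "S6"}


def _phase_integral(times, period_fn):
    """phi(t) = integral dt / T(t), cumulative trapezoid on the frame grid."""
    rate = 1.0 / period_fn(times)
    phi = np.concatenate([[0.0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]) * np.diff(times))])
    return phi


def breathing_track(scenario, n_frames, fps=11.0, amplitude=BASE_AMPLITUDE,
                    period=BASE_PERIOD, seed=None, jitter=0.0) -> BreathingTrack:
    """Coefficient tracks c_k(t) for one motion scenario.

    The scan starts at end-expiration (all coefficients zero at t = 0); the
    surrogate signal s(t) equals the SI coefficient c_1(t) in mm.  Optional
    seeded Gaussian amplitude jitter (fraction ``jitter``) perturbs A(t)
    reproducibly.
    """
    if scenario not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id: {scenario!r}")
    sid = _ALIASES.get(scenario, scenario)
    if n_frames < 1:
        raise ValueError("need at least one frame")
    t = np.arange(int(n_frames), dtype=np.float64) / fps
    t_scan = max(t[-1], 1e-9)
    A = np.full_like(t, amplitude)
    d = np.zeros_like(t)
    if sid == "static":
        c1 = c2 = c3 = np.zeros_like(t)
        coeffs = np.stack([c1, c2, c3], axis=1)
        return BreathingTrack(t, coeffs, scenario, coeffs[:, 0].copy())
    if sid == "S1":
        d = np.where(t > t_scan / 2.0, 3.0, 0.0)
        phi = t / period
    elif sid == "S2":
        d = np.where(t > t_scan / 2.0, 8.0, 0.0)
        phi = t / period
    elif sid == "S3":
        phi = t / (0.7 * period)     # onboard period 3.5 s vs 5 s prior
    elif sid == "S4":
        A = amplitude * (1.0 + 0.3 * np.sin(2 * np.pi * t / 17.0))
        d = 3.0 * t / t_scan
        phi = t / period
    elif sid == "S5":
        A = amplitude * (1.0 + 0.3 * np.sin(2 * np.pi * t / 13.0))
        phi = _phase_integral(
            t, lambda tt: period + 1.5 * np.sin(2 * np.pi * tt / 23.0))
    elif sid == "S6":
        # single slow, non-repeating excursion (monotone non-decreasing)
        r = t / t_scan
        c1 = 1.2 * amplitude * r
        c2 = 0.35 * amplitude * r ** 2
        c3 = 0.2 * amplitude * r ** 3
        coeffs = np.stack([c1, c2, c3], axis=1)
        return BreathingTrack(t, coeffs, scenario, coeffs[:, 0].copy())
    else:  # S7 / S8 share the S1 motion; anatomy differs
        d = np.where(t > t_scan / 2.0, 3.0, 0.0)
        phi = t / period
    if jitter > 0.0:
        rng = np.random.default_rng(0 if seed is None else seed)
        cyc = np.floor(phi).astype(int)
        per_cycle = 1.0 + jitter * rng.standard_normal(int(cyc.max()) + 1)
        A = A * per_cycle[cyc]
    s2 = np.sin(np.pi * phi) ** 2
    c1 = A * s2 + d
    c2 = 0.35 * A * s2 ** 2 + 0.25 * d
    c3 = 0.2 * A * np.sin(2 * np.pi * phi) ** 2
    coeffs = np.stack([c1, c2, c3], axis=1)
    return BreathingTrack(t, coeffs, scenario, coeffs[:, 0].copy())


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthFrame:
    volume: Volume
    dvf_gt: np.ndarray      # (nx, ny, nz, 3) mm, pull-back into the reference
    tumor_mask: np.ndarray  # bool
    timestamp: float


def compose_basis_dvf(basis_fields, coeffs):
    """D(x) = sum_k c_k b_k(x); basis_fields (K, nx, ny, nz, 3)."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if len(coeffs) != basis_fields.shape[0]:
        raise ValueError("coefficient count must match basis size")
    return np.tensordot(coeffs, basis_fields, axes=(0, 0))


def render_frame(ref: Volume, basis_fields, coeffs, timestamp=0.0
                 ) -> GroundTruthFrame:
    """Backward-warp the reference anatomy by the composed displacement.

    ``basis_fields`` must be evaluated on the reference grid.  The tumor
    mask is propagated by warping its indicator and re-binarizing at 0.5.
    """
    dvf = compose_basis_dvf(basis_fields, coeffs)
    vol = warp_volume(ref, dvf)
    ind = make_volume(ref.masks["tumor"].astype(np.float32), ref.spacing,
                      ref.origin)
    mask = warp_volume(ind, dvf).data >= 0.5
    return GroundTruthFrame(vol, dvf, mask, float(timestamp))


def generate_prior_4dct(params: AnatomyParams, basis: MotionBasis,
                        n_phases=10, amplitude=BASE_AMPLITUDE):
    """The prior 10-phase 4D set sampled over one 5 s sin^2 breathing cycle.

    Phase 0 is end-expiration and equals the reference anatomy; the returned
    DVFs map the EE phase to each other phase (9 fields for 10 phases), all
    lying exactly in span{b_k}.
    """
    ref = build_reference_anatomy(params)
    fields = basis.evaluate(ref.shape, ref.spacing, ref.origin)
    phases, dvfs = [], []
    phase_pts = np.arange(n_phases) / n_phases
    s2 = np.sin(np.pi * phase_pts) ** 2
    # the three tracks (sin^2, sin^4, sin^6 of the phase) are linearly
    # independent over the phase grid, so the prior phase set excites all
    # K basis fields and the PCA model spans the full intra-scan motion
    # space (note sin^2 of the double angle would NOT qualify: it is a
    # combination of sin^2 and sin^4)
    c1 = amplitude * s2
    c2 = 0.35 * amplitude * s2 ** 2
    c3 = 0.2 * amplitude * s2 ** 3
    for p in range(n_phases):
        coeffs = np.array([c1[p], c2[p], c3[p]])[: basis.k]
        if p == 0:
            phases.append(ref)
        else:
            frame = render_frame(ref, fields, coeffs)
            phases.append(frame.volume)
            dvfs.append(frame.dvf_gt)
    return ref, phases, dvfs, np.stack([c1, c2, c3], axis=1)


def onboard_params(scenario, params: AnatomyParams) -> AnatomyParams:
    """Apply the inter-scan anatomy change of S7/S8 to the prior anatomy."""
    if scenario == "S7":
        return replace(params, tumor_radius=params.tumor_radius / 2.0)
    if scenario == "S8":
        return replace(params, tumor_center=tuple(
            np.asarray(params.tumor_center) + 6.0))
    return params


def generate_dynamic_sequence(scenario, params: AnatomyParams,
                              basis: MotionBasis, n_frames=660, fps=11.0,
                              amplitude=BASE_AMPLITUDE, seed=None, jitter=0.0):
    """Ground-truth frames (one per projection time) plus the breathing track.

    For S7/S8 the inter-scan anatomy change is applied to the onboard
    reference before motion, while the prior 4D set keeps the original
    anatomy.
    """
    track = breathing_track(scenario, n_frames, fps, amplitude=amplitude,
                            seed=seed, jitter=jitter)
    ob_params = onboard_params(scenario, params)
    ref = build_reference_anatomy(ob_params)
    fields = basis.evaluate(ref.shape, ref.spacing, ref.origin)
    frames = []
    for i in range(len(track.times)):
        frames.append(render_frame(ref, fields, track.coeffs[i, : basis.k],
                                   timestamp=track.times[i]))
    return ref, frames, track
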