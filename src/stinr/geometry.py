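"""Cone-beam scan geometry, ray-driven projector, FDK reconstruction.

The scanner model is a full-fan circular trajectory: the x-ray source rotates
in the axial (x-y) plane about the SI (z) axis, with a flat-panel detector
opposite.  The forward projector ``A`` samples the volume along each
source-to-pixel ray with trilinear interpolation at a fixed step (a Joseph-
style ray-driven discretization); the backprojector is the exact adjoint of
that same discretization, which keeps algebraic solvers and gradient-based
fitting consistent with the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit, prange

from .volume import Volume, make_volume

__all__ = [
    "ScanGeometry", "ProjectionSet", "gantry_angles", "forward_project",
    "backproject", "fdk_reconstruct", "add_poisson_noise",
]


@dataclass
class ScanGeometry:
    """Acquisition geometry and timing.

    Defaults follow the clinical full-fan protocol: source-to-isocenter
    1000 mm, source-to-detector 1500 mm, 6 deg/s rotation, 11 frames/s,
    360 degree scan.  The detector defaults are desk-scale (64^2 pixels);
    the full 512^2 panel at 1.17 mm pitch is available via
    :meth:`full_scale`.
    """

    sid: float = 1000.0            # source-to-isocenter distance, mm
    sdd: float = 1500.0            # source-to-detector distance, mm
    det_shape: tuple = (64, 64)    # pixels (u = in-plane, v = axial/SI)
    pixel_pitch: tuple = (4.7, 4.7)  # mm at the detector
    rotation_speed: float = 6.0    # deg/s
    frame_rate: float = 11.0       # frames/s
    scan_range: float = 360.0      # deg
    ray_step: float | None = None  # sampling step along rays, mm

    def __post_init__(self):
        if not (self.sdd > self.sid > 0):
            raise ValueError("need SDD > SID > 0")
        if min(self.pixel_pitch) <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.rotation_speed <= 0 or self.frame_rate <= 0:
            raise ValueError("rates must be positive")

    @classmethod
    def full_scale(cls, **kw):
        return cls(det_shape=(512, 512), pixel_pitch=(1.17, 1.17), **kw)

    @property
    def n_frames_full_scan(self):
        """Frames acquired over the full scan range at the set rates."""
        duration = self.scan_range / self.rotation_speed
        return int(round(duration * self.frame_rate))

    @property
    def scan_duration(self):
        return self.scan_range / self.rotation_speed

    def with_detector(self, det_shape, pixel_pitch):
        return replace(self, det_shape=tuple(det_shape),
                       pixel_pitch=tuple(pixel_pitch))


@dataclass
class ProjectionSet:
    """Stack of line-integral images with per-frame angle and timestamp."""

    images: np.ndarray        # (n_frames, nu, nv), dimensionless line integrals
    angles_deg: np.ndarray    # (n_frames,)
    times_s: np.ndarray       # (n_frames,)
    frame_index: np.ndarray   # (n_frames,) 1-based acquisition frame numbers
    geometry: ScanGeometry

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.frame_index = np.asarray(self.frame_index)
        n = len(self.images)
        if not (len(self.angles_deg) == len(self.times_s)
                == len(self.frame_index) == n):
            raise ValueError("per-frame metadata lengths disagree")

    def __len__(self):
        return len(self.images)

    def subset(self, idx):
        return ProjectionSet(self.images[idx], self.angles_deg[idx],
                             self.times_s[idx], self.frame_index[idx],
                             self.geometry)


def gantry_angles(n_frames, frame_rate=11.0, rotation_speed=6.0):
    """Gantry angle (deg) per acquisition frame N = 1..n_frames.

    alpha_N = rotation_speed / frame_rate * (N - 1).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if frame_rate <= 0 or rotation_speed <= 0:
        raise ValueError("rates must be positive")
    n = np.arange(1, int(n_frames) + 1, dtype=np.float64)
    return (1.0 / frame_rate) * rotation_speed * (n - 1)


def frame_times(n_frames, frame_rate=11.0):
    """Timestamp (s) of each frame; frame 1 acquired at t = 0."""
    return np.arange(int(n_frames), dtype=np.float64) / frame_rate


# ---------------------------------------------------------------------------
# ray-driven kernels
# ---------------------------------------------------------------------------

@njit(cache=True, parallel=True)
def _project_view(vol, sp, org, src, det_org, u_step, v_step, nu, nv, step):
    out = np.zeros((nu, nv))
    nx, ny, nz = vol.shape
    b0x, b0y, b0z = org[0] - sp[0], org[1] - sp[1], org[2] - sp[2]
    b1x, b1y, b1z = org[0] + nx * sp[0], org[1] + ny * sp[1], org[2] + nz * sp[2]
    for p in prange(nu * nv):
        iu = p // nv
        iv = p % nv
        px = det_org[0] + iu * u_step[0] + iv * v_step[0]
        py = det_org[1] + iu * u_step[1] + iv * v_step[1]
        pz = det_org[2] + iu * u_step[2] + iv * v_step[2]
        dx, dy, dz = px - src[0], py - src[1], pz - src[2]
        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx, dy, dz = dx / norm, dy / norm, dz / norm
        # slab intersection with the (padded) volume box
        tmin, tmax = 0.0, norm
        for axis in range(3):
            d = dx if axis == 0 else (dy if axis == 1 else dz)
            o = src[axis]
            lo = b0x if axis == 0 else (b0y if axis == 1 else b0z)
            hi = b1x if axis == 0 else (b1y if axis == 1 else b1z)
            if abs(d) < 1e-12:
                if o < lo or o > hi:
                    tmin, tmax = 1.0, 0.0
            else:
                t0 = (lo - o) / d
                t1 = (hi - o) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tmin:
                    tmin = t0
                if t1 < tmax:
                    tmax = t1
        if tmax <= tmin:
            continue
        nsteps = int((tmax - tmin) / step) + 1
        dt = (tmax - tmin) / nsteps
        acc = 0.0
        for s in range(nsteps):
            t = tmin + (s + 0.5) * dt
            wx = src[0] + t * dx
            wy = src[1] + t * dy
            wz = src[2] + t * dz
            gx = (wx - org[0]) / sp[0]
            gy = (wy - org[1]) / sp[1]
            gz = (wz - org[2]) / sp[2]
            ix = int(np.floor(gx))
            iy = int(np.floor(gy))
            iz = int(np.floor(gz))
            fx, fy, fz = gx - ix, gy - iy, gz - iz
            for cx in range(2):
                jx = ix + cx
                if jx < 0 or jx >= nx:
                    continue
                wxc = fx if cx == 1 else 1.0 - fx
                for cy in range(2):
                    jy = iy + cy
                    if jy < 0 or jy >= ny:
                        continue
                    wyc = fy if cy == 1 else 1.0 - fy
                    for cz in range(2):
                        jz = iz + cz
                        if jz < 0 or jz >= nz:
                            continue
                        wzc = fz if cz == 1 else 1.0 - fz
                        acc += vol[jx, jy, jz] * wxc * wyc * wzc
        out[iu, iv] = acc * dt
    return out


@njit(cache=True)
def _backproject_view(img, vol_shape, sp, org, src, det_org, u_step, v_step,
                      step):
    nx, ny, nz = vol_shape
    out = np.zeros((nx, ny, nz))
    nu, nv = img.shape
    b0x, b0y, b0z = org[0] - sp[0], org[1] - sp[1], org[2] - sp[2]
    b1x, b1y, b1z = org[0] + nx * sp[0], org[1] + ny * sp[1], org[2] + nz * sp[2]
    for iu in range(nu):
        for iv in range(nv):
            val = img[iu, iv]
            if val == 0.0:
                continue
            px = det_org[0] + iu * u_step[0] + iv * v_step[0]
            py = det_org[1] + iu * u_step[1] + iv * v_step[1]
            pz = det_org[2] + iu * u_step[2] + iv * v_step[2]
            dx, dy, dz = px - src[0], py - src[1], pz - src[2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx, dy, dz = dx / norm, dy / norm, dz / norm
            tmin, tmax = 0.0, norm
            for axis in range(3):
                d = dx if axis == 0 else (dy if axis == 1 else dz)
                o = src[axis]
                lo = b0x if axis == 0 else (b0y if axis == 1 else b0z)
                hi = b1x if axis == 0 else (b1y if axis == 1 else b1z)
                if abs(d) < 1e-12:
                    if o < lo or o > hi:
                        tmin, tmax = 1.0, 0.0
                else:
                    t0 = (lo - o) / d
                    t1 = (hi - o) / d
                    if t0 > t1:
                        t0, t1 = t1, t0
                    if t0 > tmin:
                        tmin = t0
                    if t1 < tmax:
                        tmax = t1
            if tmax <= tmin:
                continue
            nsteps = int((tmax - tmin) / step) + 1
            dt = (tmax - tmin) / nsteps
            w = val * dt
            for s in range(nsteps):
                t = tmin + (s + 0.5) * dt
                wx = src[0] + t * dx
                wy = src[1] + t * dy
                wz = src[2] + t * dz
                gx = (wx - org[0]) / sp[0]
                gy = (wy - org[1]) / sp[1]
                gz = (wz - org[2]) / sp[2]
                ix = int(np.floor(gx))
                iy = int(np.floor(gy))
                iz = int(np.floor(gz))
                fx, fy, fz = gx - ix, gy - iy, gz - iz
                for cx in range(2):
                    jx = ix + cx
                    if jx < 0 or jx >= nx:
                        continue
                    wxc = fx if cx == 1 else 1.0 - fx
                    for cy in range(2):
                        jy = iy + cy
                        if jy < 0 or jy >= ny:
                            continue
                        wyc = fy if cy == 1 else 1.0 - fy
                        for cz in range(2):
                            jz = iz + cz
                            if jz < 0 or jz >= nz:
                                continue
                            wzc = fz if cz == 1 else 1.0 - fz
                            out[jx, jy, jz] += w * wxc * wyc * wzc
    return out


def _view_frames(geometry: ScanGeometry, angles_deg):
    """Per-view source position, detector-origin, and pixel step vectors."""
    ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    nu, nv = geometry.det_shape
    pu, pv = geometry.pixel_pitch
    cos, sin = np.cos(ang), np.sin(ang)
    src = np.stack([geometry.sid * cos, geometry.sid * sin,
                    np.zeros_like(ang)], axis=1)
    center = np.stack([(geometry.sid - geometry.sdd) * cos,
                       (geometry.sid - geometry.sdd) * sin,
                       np.zeros_like(ang)], axis=1)
    u_vec = np.stack([-sin, cos, np.zeros_like(ang)], axis=1)
    v_vec = np.tile(np.array([0.0, 0.0, 1.0]), (len(ang), 1))
    det_org = (center - u_vec * (nu - 1) / 2.0 * pu
               - v_vec * (nv - 1) / 2.0 * pv)
    return src, det_org, u_vec * pu, v_vec * pv


def _ray_step(geometry: ScanGeometry, vol: Volume):
    if geometry.ray_step is not None:
        return float(geometry.ray_step)
    return 0.5 * float(np.min(vol.spacing))


def forward_project(vol: Volume, geometry: ScanGeometry, angles_deg,
                    times_s=None, frame_index=None):
    """Line integrals of ``vol`` for each gantry angle.

    Each pixel holds the integral of attenuation (mm^-1) along the
    source-to-pixel ray, in mm^-1 * mm (dimensionless); the operation is
    linear in the volume.
    """
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=np.float64))
    if not np.all(np.isfinite(angles_deg)):
        raise ValueError("angles must be finite")
    nu, nv = geometry.det_shape
    src, det_org, u_step, v_step = _view_frames(geometry, angles_deg)
    step = _ray_step(geometry, vol)
    data = np.ascontiguousarray(vol.data, dtype=np.float64)
    sp = np.ascontiguousarray(vol.spacing)
    org = np.ascontiguousarray(vol.origin)
    images = np.empty((len(angles_deg), nu, nv))
    for i in range(len(angles_deg)):
        images[i] = _project_view(data, sp, org, src[i], det_org[i],
                                  u_step[i], v_step[i], nu, nv, step)
    if times_s is None:
        times_s = frame_times(len(angles_deg), geometry.frame_rate)
    if frame_index is None:
        frame_index = np.arange(1, len(angles_deg) + 1)
    return ProjectionSet(images, angles_deg, times_s, frame_index, geometry)


def project_view(vol_data, spacing, origin, geometry: ScanGeometry, angle_deg,
                 step):
    """Single-view forward projection on raw arrays (training inner loop)."""
    src, det_org, u_step, v_step = _view_frames(geometry, [angle_deg])
    nu, nv = geometry.det_shape
    return _project_view(np.ascontiguousarray(vol_data, dtype=np.float64),
                         np.ascontiguousarray(spacing),
                         np.ascontiguousarray(origin),
                         src[0], det_org[0], u_step[0], v_step[0], nu, nv, step)


def backproject_view(img, vol_shape, spacing, origin, geometry: ScanGeometry,
                     angle_deg, step):
    """Single-view adjoint of :func:`project_view`."""
    src, det_org, u_step, v_step = _view_frames(geometry, [angle_deg])
    return _backproject_view(np.ascontiguousarray(img, dtype=np.float64),
                             tuple(int(s) for s in vol_shape),
                             np.ascontiguousarray(spacing),
                             np.ascontiguousarray(origin),
                             src[0], det_org[0], u_step[0], v_step[0], step)


def backproject(projections: ProjectionSet, grid: Volume):
    """Exact adjoint A^T of :func:`forward_project` on the same grid."""
    geometry = projections.geometry
    step = _ray_step(geometry, grid)
    out = np.zeros(grid.shape)
    for i in range(len(projections)):
        out += backproject_view(projections.images[i], grid.shape,
                                grid.spacing, grid.origin, geometry,
                                projections.angles_deg[i], step)
    return Volume(out, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# FDK
# ---------------------------------------------------------------------------

def _ramp_kernel(n, du):
    """Spatial-domain band-limited ramp (Ram-Lak) kernel, length 2n+1."""
    k = np.arange(-n, n + 1)
    h = np.zeros(2 * n + 1)
    h[n] = 1.0 / (4.0 * du * du)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * du) ** 2
    return h


def _filter_rows(images, du, apodize=True):
    """Cosine-weighted images -> ramp-filtered along u (axis 1)."""
    nf, nu, nv = images.shape
    pad = 1 << int(np.ceil(np.log2(4 * nu)))
    h = _ramp_kernel(nu, du)
    H = np.fft.rfft(h, pad)
    if apodize:
        # raised-cosine apodization over the top octave only: flat passband
        # to half-Nyquist, cosine taper to zero at Nyquist.  A full-band Hann
        # window costs too much resolution at desk-scale detector pitches.
        freqs = np.fft.rfftfreq(pad)
        window = np.ones_like(freqs)
        hi = freqs > 0.25
        window[hi] = 0.5 * (1.0 + np.cos(np.pi * (freqs[hi] - 0.25) / 0.25))
        H = H * window
    spec = np.fft.rfft(images, pad, axis=1)
    filt = np.fft.irfft(spec * H[None, :, None], pad, axis=1)
    return filt[:, nu:2 * nu, :] * du


@njit(cache=True, parallel=True)
def _fdk_backproject(filtered, cosang, sinang, sid, du_iso, dv_iso,
                     nx, ny, nz, sp, org):
    nviews, nu, nv = filtered.shape
    out = np.zeros((nx, ny, nz))
    cu = (nu - 1) / 2.0
    cv = (nv - 1) / 2.0
    for p in prange(nx * ny):
        i = p // ny
        j = p % ny
        x = org[0] + i * sp[0]
        y = org[1] + j * sp[1]
        for v in range(nviews):
            U = sid - (x * cosang[v] + y * sinang[v])
            if U <= 1e-6:
                continue
            w = sid * sid / (U * U)
            uu = sid * (-x * sinang[v] + y * cosang[v]) / U
            fu = uu / du_iso + cu
            if fu < 0.0 or fu > nu - 1.0:
                continue
            iu = int(fu)
            if iu > nu - 2:
                iu = nu - 2
            au = fu - iu
            for k in range(nz):
                z = org[2] + k * sp[2]
                vv = sid * z / U
                fv = vv / dv_iso + cv
                if fv < 0.0 or fv > nv - 1.0:
                    continue
                iv = int(fv)
                if iv > nv - 2:
                    iv = nv - 2
                av = fv - iv
                val = ((1 - au) * (1 - av) * filtered[v, iu, iv]
                       + au * (1 - av) * filtered[v, iu + 1, iv]
                       + (1 - au) * av * filtered[v, iu, iv + 1]
                       + au * av * filtered[v, iu + 1, iv + 1])
                out[i, j, k] += w * val
    return out


def fdk_reconstruct(projections: ProjectionSet, grid: Volume,
                    apodize=True):
    """Feldkamp-Davis-Kress reconstruction onto ``grid``.

    Cosine weighting, row-wise ramp filtering with raised-cosine
    apodization, then distance-weighted backprojection.  Full-scan weighting
    (angular increments measured from the supplied angle list); deterministic.
    """
    if len(projections) < 2:
        raise ValueError("FDK needs at least 2 views")
    geom = projections.geometry
    sid, sdd = geom.sid, geom.sdd
    nu, nv = geom.det_shape
    mag = sid / sdd
    du_iso = geom.pixel_pitch[0] * mag
    dv_iso = geom.pixel_pitch[1] * mag
    u = (np.arange(nu) - (nu - 1) / 2.0) * du_iso
    v = (np.arange(nv) - (nv - 1) / 2.0) * dv_iso
    cosw = sid / np.sqrt(sid ** 2 + u[:, None] ** 2 + v[None, :] ** 2)
    weighted = projections.images * cosw[None, :, :]
    filtered = _filter_rows(weighted, du_iso, apodize=apodize)
    ang = np.deg2rad(projections.angles_deg)
    # average angular increment; full-scan 360 deg counts each ray twice
    span = np.ptp(ang)
    d_ang = span / max(len(projections) - 1, 1)
    scale = d_ang / 2.0
    nx, ny, nz = grid.shape
    out = _fdk_backproject(np.ascontiguousarray(filtered),
                           np.cos(ang), np.sin(ang), sid, du_iso, dv_iso,
                           nx, ny, nz,
                           np.ascontiguousarray(grid.spacing),
                           np.ascontiguousarray(grid.origin))
    return Volume(out * scale, grid.spacing.copy(), grid.origin.copy())


def add_poisson_noise(projections: ProjectionSet, i0, seed=0,
                      floor_counts=0.5):
    """Transmission Poisson noise at incident fluence ``i0`` photons/pixel.

    p -> -ln(max(Poisson(i0 * exp(-p)), floor) / i0), seeded and reproducible.
    """
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    rng = np.random.default_rng(seed)
    expected = i0 * np.exp(-projections.images)
    counts = rng.poisson(expected).astype(np.float64)
    counts = np.maximum(counts, floor_counts)
    noisy = -np.log(counts / i0)
    return ProjectionSet(noisy, projections.angles_deg.copy(),
                         projections.times_s.copy(),
                         projections.frame_index.copy(), projections.geometry)
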