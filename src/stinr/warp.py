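"""Differentiable trilinear warping / resampling.

The pull-back convention is used throughout: a displacement field D (mm),
sampled on the *output* grid, maps output coordinates into the input volume,

    out(x) = in(x + D(x)).

numba kernels provide the gather (interpolation), its adjoint scatter, and
the spatial gradient of the interpolant — the three pieces needed to
backpropagate a voxelwise loss through a warp to both the source volume and
the displacement field.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .volume import Volume


@njit(cache=True)
def trilinear_gather(vol, pts):
    """Sample ``vol`` at fractional voxel coords ``pts`` (N, 3), edge-clamped."""
    nx, ny, nz = vol.shape
    n = pts.shape[0]
    out = np.empty(n, dtype=vol.dtype)
    for i in range(n):
        px = min(max(pts[i, 0], 0.0), nx - 1.0)
        py = min(max(pts[i, 1], 0.0), ny - 1.0)
        pz = min(max(pts[i, 2], 0.0), nz - 1.0)
        ix = min(int(px), nx - 2) if nx > 1 else 0
        iy = min(int(py), ny - 2) if ny > 1 else 0
        iz = min(int(pz), nz - 2) if nz > 1 else 0
        fx, fy, fz = px - ix, py - iy, pz - iz
        c00 = vol[ix, iy, iz] * (1 - fx) + vol[min(ix + 1, nx - 1), iy, iz] * fx
        c10 = vol[ix, min(iy + 1, ny - 1), iz] * (1 - fx) \
            + vol[min(ix + 1, nx - 1), min(iy + 1, ny - 1), iz] * fx
        c01 = vol[ix, iy, min(iz + 1, nz - 1)] * (1 - fx) \
            + vol[min(ix + 1, nx - 1), iy, min(iz + 1, nz - 1)] * fx
        c11 = vol[ix, min(iy + 1, ny - 1), min(iz + 1, nz - 1)] * (1 - fx) \
            + vol[min(ix + 1, nx - 1), min(iy + 1, ny - 1), min(iz + 1, nz - 1)] * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        out[i] = c0 * (1 - fz) + c1 * fz
    return out


@njit(cache=True)
def trilinear_scatter(shape_x, shape_y, shape_z, pts, vals):
    """Adjoint of :func:`trilinear_gather`: splat ``vals`` into a zero volume."""
    out = np.zeros((shape_x, shape_y, shape_z), dtype=np.float64)
    nx, ny, nz = shape_x, shape_y, shape_z
    n = pts.shape[0]
    for i in range(n):
        px = min(max(pts[i, 0], 0.0), nx - 1.0)
        py = min(max(pts[i, 1], 0.0), ny - 1.0)
        pz = min(max(pts[i, 2], 0.0), nz - 1.0)
        ix = min(int(px), nx - 2) if nx > 1 else 0
        iy = min(int(py), ny - 2) if ny > 1 else 0
        iz = min(int(pz), nz - 2) if nz > 1 else 0
        fx, fy, fz = px - ix, py - iy, pz - iz
        jx = min(ix + 1, nx - 1)
        jy = min(iy + 1, ny - 1)
        jz = min(iz + 1, nz - 1)
        v = vals[i]
        out[ix, iy, iz] += v * (1 - fx) * (1 - fy) * (1 - fz)
        out[jx, iy, iz] += v * fx * (1 - fy) * (1 - fz)
        out[ix, jy, iz] += v * (1 - fx) * fy * (1 - fz)
        out[jx, jy, iz] += v * fx * fy * (1 - fz)
        out[ix, iy, jz] += v * (1 - fx) * (1 - fy) * fz
        out[jx, iy, jz] += v * fx * (1 - fy) * fz
        out[ix, jy, jz] += v * (1 - fx) * fy * fz
        out[jx, jy, jz] += v * fx * fy * fz
    return out


@njit(cache=True)
def trilinear_gather_grad(vol, pts):
    """Gradient of the interpolant w.r.t. the sample position, (N, 3).

    Zero where the position is edge-clamped (the interpolant is constant
    beyond the boundary under the clamping policy).
    """
    nx, ny, nz = vol.shape
    n = pts.shape[0]
    out = np.zeros((n, 3), dtype=np.float64)
    for i in range(n):
        clx = pts[i, 0] <= 0.0 or pts[i, 0] >= nx - 1.0
        cly = pts[i, 1] <= 0.0 or pts[i, 1] >= ny - 1.0
        clz = pts[i, 2] <= 0.0 or pts[i, 2] >= nz - 1.0
        px = min(max(pts[i, 0], 0.0), nx - 1.0)
        py = min(max(pts[i, 1], 0.0), ny - 1.0)
        pz = min(max(pts[i, 2], 0.0), nz - 1.0)
        ix = min(int(px), nx - 2) if nx > 1 else 0
        iy = min(int(py), ny - 2) if ny > 1 else 0
        iz = min(int(pz), nz - 2) if nz > 1 else 0
        fx, fy, fz = px - ix, py - iy, pz - iz
        jx = min(ix + 1, nx - 1)
        jy = min(iy + 1, ny - 1)
        jz = min(iz + 1, nz - 1)
        v000 = vol[ix, iy, iz]
        v100 = vol[jx, iy, iz]
        v010 = vol[ix, jy, iz]
        v110 = vol[jx, jy, iz]
        v001 = vol[ix, iy, jz]
        v101 = vol[jx, iy, jz]
        v011 = vol[ix, jy, jz]
        v111 = vol[jx, jy, jz]
        if not clx:
            out[i, 0] = ((v100 - v000) * (1 - fy) * (1 - fz)
                         + (v110 - v010) * fy * (1 - fz)
                         + (v101 - v001) * (1 - fy) * fz
                         + (v111 - v011) * fy * fz)
        if not cly:
            out[i, 1] = ((v010 - v000) * (1 - fx) * (1 - fz)
                         + (v110 - v100) * fx * (1 - fz)
                         + (v011 - v001) * (1 - fx) * fz
                         + (v111 - v101) * fx * fz)
        if not clz:
            out[i, 2] = ((v001 - v000) * (1 - fx) * (1 - fy)
                         + (v101 - v100) * fx * (1 - fy)
                         + (v011 - v010) * (1 - fx) * fy
                         + (v111 - v110) * fx * fy)
    return out


def _sample_points(grid_shape, grid_spacing, grid_origin, dvf,
                   src_spacing, src_origin):
    """Fractional source-voxel coordinates of each output voxel after warp."""
    shape = tuple(int(s) for s in grid_shape)
    axes = [grid_origin[a] + grid_spacing[a] * np.arange(shape[a])
            for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    world = np.stack([a.ravel() for a in g], axis=1)
    world = world + dvf.reshape(-1, 3)
    return (world - src_origin) / src_spacing


def warp_volume(vol: Volume, dvf, grid=None):
    """Backward-warp ``vol`` by displacement field ``dvf``.

    Parameters
    ----------
    vol : Volume
        Source volume.
    dvf : (nx, ny, nz, 3) ndarray
        Pull-back displacement in mm, sampled on the output grid.
    grid : Volume or None
        Defines the output grid; defaults to the source grid.

    Out-of-bounds samples clamp to edge values (no NaNs).
    """
    ref = vol if grid is None else grid
    dvf = np.asarray(dvf, dtype=np.float64)
    if dvf.shape != (*ref.shape, 3):
        raise ValueError("dvf must be sampled on the output grid, (nx,ny,nz,3)")
    pts = _sample_points(ref.shape, ref.spacing, ref.origin, dvf,
                         vol.spacing, vol.origin)
    out = trilinear_gather(np.ascontiguousarray(vol.data, dtype=np.float64),
                           np.ascontiguousarray(pts))
    return Volume(out.reshape(ref.shape).astype(vol.data.dtype, copy=False),
                  ref.spacing.copy(), ref.origin.copy())


def warp_backward(vol_data, spacing, pts, dout):
    """Gradients of ``sum(dout * gather(vol, pts))`` w.r.t. volume and DVF.

    Returns ``(d_vol, d_dvf_mm)`` where ``d_dvf_mm`` is per-point (N, 3) in
    1/mm units (chain rule through the voxel-coordinate scaling).
    """
    vol64 = np.ascontiguousarray(vol_data, dtype=np.float64)
    pts = np.ascontiguousarray(pts)
    dout = np.ascontiguousarray(dout, dtype=np.float64).ravel()
    d_vol = trilinear_scatter(vol64.shape[0], vol64.shape[1], vol64.shape[2],
                              pts, dout)
    g = trilinear_gather_grad(vol64, pts)
    d_dvf = g * dout[:, None] / np.asarray(spacing)[None, :]
    return d_vol, d_dvf
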