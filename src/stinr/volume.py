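"""Voxelized attenuation volumes with physical-space metadata.

Arrays are indexed ``(x, y, z)`` with the z axis along the superior-inferior
(SI) direction, which is also the gantry rotation axis.  Attenuation is stored
in mm^-1.  World coordinates are millimetres; voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """Attenuation (or label) map on a regular grid.

    Attributes
    ----------
    data : (nx, ny, nz) ndarray
        Voxel values; attenuation in mm^-1 for image volumes.
    spacing : (3,) ndarray
        Voxel size in mm per axis.
    origin : (3,) ndarray
        World coordinate (mm) of voxel (0, 0, 0).
    masks : dict
        Optional per-tissue boolean label masks on the same grid.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def extent(self):
        """Physical size n*spacing (mm) per axis."""
        return np.asarray(self.shape) * self.spacing

    def copy(self, data=None):
        return Volume(
            self.data.copy() if data is None else np.asarray(data),
            self.spacing.copy(),
            self.origin.copy(),
            {k: v.copy() for k, v in self.masks.items()},
        )

    def world_coords(self):
        """World coordinates (mm) of all voxel centers, shape (nx, ny, nz, 3)."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def world_to_voxel(self, pts):
        return (np.asarray(pts) - self.origin) / self.spacing

    def voxel_to_world(self, idx):
        return self.origin + np.asarray(idx) * self.spacing


def centered_grid(shape, spacing):
    """Origin placing the grid center at the world origin (isocenter)."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = -(shape - 1) / 2.0 * spacing
    return origin


def make_volume(data, spacing, origin=None, masks=None):
    data = np.asarray(data)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    if origin is None:
        origin = centered_grid(data.shape, spacing)
    return Volume(data, spacing, origin, masks or {})


def resample_to_grid(vol: Volume, shape, spacing, origin=None, order=1):
    """Trilinearly resample a volume onto another grid over the same space."""
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    if origin is None:
        origin = centered_grid(shape, spacing)
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(g, axis=0)  # (3, nx, ny, nz) world
    idx = [(pts[a] - vol.origin[a]) / vol.spacing[a] for a in range(3)]
    out = ndimage.map_coordinates(vol.data.astype(np.float64), idx, order=order,
                                  mode="nearest")
    return Volume(out.astype(vol.data.dtype, copy=False), spacing,
                  np.asarray(origin, dtype=np.float64))
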