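"""Persistence: NIfTI volumes, HDF5 projections/models/checkpoints, CSV tracks."""

from __future__ import annotations

import csv

import h5py
import nibabel as nib
import numpy as np

from .geometry import ProjectionSet, ScanGeometry
from .inr import GRFFEncoder, MLP, SpatialINR, TemporalINR
from .motion import MotionModel
from .volume import Volume

__all__ = [
    "save_volume_nifti", "load_volume_nifti", "save_projections",
    "load_projections", "save_motion_model", "load_motion_model",
    "save_track_csv", "load_track_csv", "save_checkpoint", "load_checkpoint",
]


def save_volume_nifti(path, vol: Volume, dtype=None):
    """Write a volume (or uint8 mask) as NIfTI with spacing/origin affine."""
    data = vol.data if dtype is None else vol.data.astype(dtype)
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume_nifti(path) -> Volume:
    img = nib.load(str(path))
    affine = img.affine
    return Volume(np.asarray(img.dataobj), np.abs(np.diag(affine)[:3]),
                  affine[:3, 3])


_GEOM_FIELDS = ("sid", "sdd", "rotation_speed", "frame_rate", "scan_range")


def save_projections(path, projections: ProjectionSet):
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=projections.images)
        f.create_dataset("angles_deg", data=projections.angles_deg)
        f.create_dataset("times_s", data=projections.times_s)
        f.create_dataset("frame_index", data=projections.frame_index)
        g = projections.geometry
        for k in _GEOM_FIELDS:
            f.attrs[k] = getattr(g, k)
        f.attrs["det_shape"] = g.det_shape
        f.attrs["pixel_pitch"] = g.pixel_pitch


def load_projections(path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        geom = ScanGeometry(
            det_shape=tuple(int(x) for x in f.attrs["det_shape"]),
            pixel_pitch=tuple(float(x) for x in f.attrs["pixel_pitch"]),
            **{k: float(f.attrs[k]) for k in _GEOM_FIELDS})
        return ProjectionSet(f["images"][:], f["angles_deg"][:],
                             f["times_s"][:], f["frame_index"][:], geom)


def save_motion_model(path, model: MotionModel):
    with h5py.File(path, "w") as f:
        f.create_dataset("pc0", data=model.pc0)
        f.create_dataset("components", data=model.components)
        f.create_dataset("scales", data=model.scales)
        f.attrs["spacing"] = model.spacing
        f.attrs["origin"] = model.origin


def load_motion_model(path) -> MotionModel:
    with h5py.File(path, "r") as f:
        return MotionModel(f["pc0"][:], f["components"][:], f["scales"][:],
                           np.asarray(f.attrs["spacing"]),
                           np.asarray(f.attrs["origin"]))


def save_track_csv(path, times, values, value_names):
    """Frame-indexed CSV: frame, time_s, <value columns>."""
    values = np.atleast_2d(np.asarray(values))
    if values.shape[0] != len(times):
        values = values.T
    with open(path, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["frame", "time_s", *value_names])
        for i, t in enumerate(times):
            wr.writerow([i + 1, f"{t:.6f}",
                         *(f"{v:.8g}" for v in values[i])])


def load_track_csv(path):
    with open(path, newline="") as f:
        rows = list(csv.reader(f))
    header = rows[0]
    data = np.array([[float(x) for x in r] for r in rows[1:]])
    return data[:, 1], data[:, 2:], header[2:]


def _save_mlp(group, mlp: MLP):
    group.attrs["sizes"] = mlp.sizes
    group.attrs["activation"] = mlp.activation
    for i, (w, b) in enumerate(zip(mlp.W, mlp.b)):
        group.create_dataset(f"W{i}", data=w)
        group.create_dataset(f"b{i}", data=b)


def _load_mlp(group) -> MLP:
    mlp = MLP(list(group.attrs["sizes"]), activation=group.attrs["activation"])
    n = len(mlp.W)
    mlp.W = [group[f"W{i}"][:] for i in range(n)]
    mlp.b = [group[f"b{i}"][:] for i in range(n)]
    return mlp


def _save_encoder(group, enc: GRFFEncoder):
    group.create_dataset("B", data=enc.B)
    group.attrs["sigma_b"] = enc.sigma_b
    group.attrs["seed"] = enc.seed


def save_checkpoint(path, spatial: SpatialINR, temporal: TemporalINR):
    """Serialize both INRs (parameters + frozen encoders) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        gs = f.create_group("spatial")
        gs.attrs["box_center"] = spatial.box_center
        gs.attrs["box_half"] = spatial.box_half
        _save_encoder(gs.create_group("encoder"), spatial.encoder)
        _save_mlp(gs.create_group("mlp"), spatial.mlp)
        gt = f.create_group("temporal")
        _save_encoder(gt.create_group("encoder"), temporal.encoder)
        for i, m in enumerate(temporal.mlps):
            _save_mlp(gt.create_group(f"mlp{i}"), m)


def load_checkpoint(path, preset):
    from .inr import SpatialINR, TemporalINR
    with h5py.File(path, "r") as f:
        gs = f["spatial"]
        spatial = SpatialINR(np.asarray(gs.attrs["box_center"]),
                             np.asarray(gs.attrs["box_half"]), preset=preset)
        spatial.encoder.B = gs["encoder/B"][:]
        spatial.mlp = _load_mlp(gs["mlp"])
        gt = f["temporal"]
        temporal = TemporalINR(preset=preset)
        temporal.encoder.B = gt["encoder/B"][:]
        temporal.mlps = [_load_mlp(gt[f"mlp{i}"])
                         for i in range(temporal.N_TRACKS)]
    return spatial, temporal
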