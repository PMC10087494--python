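"""Experiment configuration: schema, defaults, validation, seed fan-out."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .phantom import SCENARIO_IDS

__all__ = ["ExperimentConfig", "load_config", "save_config", "derive_seed"]

_METHODS = ("stinr", "pcacv", "inrpoly", "fdk")
_REG_MODES = ("bypass", "demons")


@dataclass
class ExperimentConfig:
    """Validated description of one end-to-end scenario run.

    Scan defaults follow the clinical protocol (SID 1000 mm, SDD 1500 mm,
    6 deg/s, 11 frames/s, full-fan 360 deg); phantom and network sizes
    default to desk scale.
    """

    scenario: str = "S1"
    method: str = "stinr"
    seed: int = 0
    # phantom / simulation grid
    sim_shape: tuple = (64, 64, 64)
    sim_spacing: float = 3.0
    n_frames: int = 660
    frame_rate: float = 11.0
    amplitude_mm: float = 10.0
    tumor_radius_mm: float = 15.0
    noise_i0: float = 0.0          # 0 disables projection noise
    # scan geometry
    sid: float = 1000.0
    sdd: float = 1500.0
    rotation_speed: float = 6.0
    det_shape: tuple = (64, 64)
    pixel_pitch: tuple = (4.7, 4.7)
    # motion model
    registration_mode: str = "bypass"
    registration_noise_mm: float = 0.0
    n_components: int = 3
    # reconstruction
    opt_shape: tuple = (32, 32, 32)
    opt_spacing: float = 6.0
    stage_iters: tuple = (500, 500, 2000)
    lr: float = 0.002
    batch_frames: int = 8
    ee_fraction: float = 0.1
    eval_shape: tuple | None = None     # defaults to the simulation grid
    output_dir: str = "stinr_run"

    def __post_init__(self):
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(
                f"scenario: unknown id {self.scenario!r}; "
                f"expected one of {SCENARIO_IDS}")
        if self.method not in _METHODS:
            raise ValueError(f"method: must be one of {_METHODS}")
        if self.registration_mode not in _REG_MODES:
            raise ValueError(f"registration_mode: must be one of {_REG_MODES}")
        for name in ("sim_spacing", "frame_rate", "rotation_speed", "sid",
                     "sdd", "opt_spacing", "lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames: must be >= 1")
        if not 0 < self.ee_fraction <= 1:
            raise ValueError("ee_fraction: must lie in (0, 1]")
        self.sim_shape = tuple(int(s) for s in self.sim_shape)
        self.opt_shape = tuple(int(s) for s in self.opt_shape)
        self.det_shape = tuple(int(s) for s in self.det_shape)
        self.pixel_pitch = tuple(float(p) for p in self.pixel_pitch)
        self.stage_iters = tuple(int(i) for i in self.stage_iters)
        if self.eval_shape is not None:
            self.eval_shape = tuple(int(s) for s in self.eval_shape)

    def to_dict(self):
        return asdict(self)

    @property
    def config_hash(self):
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master_seed, component):
    """Stable per-component sub-seed < 2^31 from the master seed."""
    h = hashlib.blake2s(f"{master_seed}:{component}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def load_config(path) -> ExperimentConfig:
    """Load a YAML config; unknown keys and invalid values raise with the
    offending field named."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def save_config(path, config: ExperimentConfig):
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)
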