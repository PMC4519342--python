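"""Pipeline configuration.

Defaults reproduce the published parameter set: 310 K, hills of 0.1 kJ/mol
with sigma 2.0 once per ps-equivalent step, CV boundaries [0, 32], a bias
grid from -5 to 42, switching parameters r0 = 0.08 nm / n = 8 / m = 12, a
half-harmonic wall at 7.0 nm with kappa = 100 kJ/mol, and a 160 x 160
free-energy grid.  Operational knobs the source material is silent about
(proposal width, MC moves per step, exchange interval) carry the package's
documented defaults.  Any override relative to the defaults is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import yaml

from . import constants as c

log = logging.getLogger("bemeta")


@dataclass
class PipelineConfig:
    temperature_k: float = c.DEFAULT_TEMPERATURE_K

    # CV switching function
    switch_r0_nm: float = c.SWITCH_R0_NM
    switch_n: int = c.SWITCH_N
    switch_m: int = c.SWITCH_M

    # hill schedule
    hill_height: float = c.HILL_HEIGHT_KJ_MOL
    hill_sigma: float = c.HILL_SIGMA
    hill_pace: int = c.HILL_PACE_STEPS
    hill_truncation: float = c.HILL_TRUNCATION_SIGMAS
    boundary_corrected: bool = True

    # grids and domain
    cv_domain: tuple = c.CV_DOMAIN
    bias_grid_range: tuple = c.BIAS_GRID_RANGE
    bias_grid_nodes_1d: int = c.BIAS_GRID_NODES_1D
    bias_grid_nodes_2d: int = c.BIAS_GRID_NODES_2D
    fes_grid_nodes: int = c.FES_GRID_NODES

    # wall
    wall_position_nm: float = c.WALL_POSITION_NM
    wall_kappa: float = c.WALL_KAPPA

    # toy sampler / exchange schedule
    n_steps: int = 20000
    mc_moves_per_step: int = 10
    proposal_sigma: float = 0.5
    exchange_interval: int = 100
    pair_selection: str = "neighbor_cycle"
    output_stride: int = 10
    seed: int = 2024

    # synthetic demo ensemble
    n_frames: int = 20000
    sequence: str = c.RIAPP_SEQUENCE
    shift_noise_sd: float = 0.3

    def __post_init__(self):
        self.cv_domain = tuple(self.cv_domain)
        self.bias_grid_range = tuple(self.bias_grid_range)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if getattr(cfg, f.name) != getattr(defaults, f.name):
                log.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)
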