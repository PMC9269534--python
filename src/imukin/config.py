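"""Run configuration: a validated bundle of every pipeline knob.

Loaded from a TOML file and/or CLI flags (flags win).  Unknown keys are
rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .rotations import EULER_ORDERS


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    accel_sigma: float = Field(default=0.05, ge=0)
    gyro_sigma: float = Field(default=0.2, ge=0)
    gyro_bias: tuple[float, float, float] = (0.5 / 3**0.5,) * 3
    mag_sigma: float = Field(default=0.5, ge=0)


class FusionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gyro_noise: float = Field(default=0.2, ge=0)
    accel_trust: float = Field(default=1.0, ge=0)
    mag_trust: float = Field(default=1.0, ge=0)
    bias_process: float = Field(default=0.01, ge=0)


class RunConfig(BaseModel):
    """Everything a subcommand needs to be reproducible from config + seed."""

    model_config = ConfigDict(extra="forbid")

    rate: Literal[30, 60, 120] = 60
    representation: Literal["euler", "quaternion"] = "quaternion"
    euler_order: str = "ZYX"
    #: mounting deltas (d1, d2) for the arm sensor and (d3, d4) for the forearm
    mount_arm: tuple[float, float] = (270.0, 0.0)
    mount_forearm: tuple[float, float] = (0.0, 0.0)
    t_cal: float = Field(default=2.0, ge=0)
    seed: int = 0
    noise: NoiseConfig = NoiseConfig()
    fusion: FusionConfig = FusionConfig()

    def model_post_init(self, _ctx) -> None:
        if self.euler_order not in EULER_ORDERS:
            raise ValueError(f"euler_order must be one of {EULER_ORDERS}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.model_validate(tomllib.load(fh))
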