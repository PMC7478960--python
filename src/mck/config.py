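"""Run configuration: a validated YAML-backed parameter set.

Every numeric default that mirrors a fixed analysis constant is taken from
:mod:`mck.constants`, which defines each exactly once. One integer seed
feeds every stochastic stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import constants


class SceneConfig(BaseModel):
    kind: Literal["spot_pair", "tubular", "mdt_event"] = "spot_pair"
    field_size: tuple[int, int] = (256, 256)
    pixel_size: float = Field(constants.PIXEL_SIZE_NM, gt=0)
    frame_interval: float = Field(1.0, gt=0)
    n_frames: int = Field(1, ge=1)
    psf_sigma: float = Field(constants.PSF_SIGMA_NM, ge=0)
    photon_scale: Optional[float] = None          # None = noiseless
    read_noise_sd: float = Field(0.0, ge=0)
    # spot_pair
    n_pairs: int = Field(100, ge=1)
    offset_sd: float = Field(50.0, ge=0)
    # tubular
    tubule_diameter: float = Field(200.0, ge=40, le=1000)
    # mdt_event
    tip_speed: float = Field(50.0, gt=0)
    coupling: Literal["coupled", "unsynchronized", "retained"] = "coupled"


class ShiftCurveConfig(BaseModel):
    channel_a: str = "spots_a"
    channel_b: str = "spots_b"
    max_shift: float = Field(640.0, gt=0)
    step: float = Field(constants.SHIFT_STEP_NM, gt=0)
    confidence: float = Field(constants.CONFIDENCE, gt=0, lt=1)


class ColocConfig(BaseModel):
    threshold: Optional[float] = None             # None: use recovered value
    n_perm: int = Field(1000, ge=1)


class ContactConfig(BaseModel):
    mito_channel: str = "mito"
    er_channel: str = "er"
    background_radius: int = Field(15, ge=1)
    method: Literal["otsu", "fixed"] = "otsu"
    cutoff: Optional[float] = None
    dilation_radius: int = Field(0, ge=0)


class TrackConfig(BaseModel):
    channel: str = "nucleoid"
    expected_sigma: float = Field(constants.PSF_SIGMA_NM, gt=0)
    min_quality: float = Field(0.3, ge=0, le=1)
    max_disp: float = Field(500.0, gt=0)


class MsdConfig(BaseModel):
    max_lag: int = Field(25, ge=4)
    fit_fraction: float = Field(0.25, gt=0, le=1)


class EventsConfig(BaseModel):
    proximity_radius: float = Field(constants.PROXIMITY_RADIUS_NM, gt=0)
    travel_min: float = Field(constants.TRAVEL_MIN_NM, gt=0)
    tip_tolerance: float = Field(constants.TIP_TOLERANCE_NM, gt=0)


class RunConfig(BaseModel):
    """Validated configuration of a pipeline run."""

    seed: int = 0
    out_dir: Path = Path("mck_out")
    overwrite: bool = False
    stages: list[Literal["simulate", "shiftcurve", "coloc", "contact",
                         "track", "msd", "events"]] = \
        Field(default_factory=lambda: ["simulate"])
    # inputs for runs starting from files instead of simulation
    stack_path: Optional[Path] = None
    lines_path: Optional[Path] = None
    points_a_path: Optional[Path] = None
    points_b_path: Optional[Path] = None
    pixel_size: Optional[float] = None
    frame_interval: Optional[float] = None

    scene: SceneConfig = SceneConfig()
    shiftcurve: ShiftCurveConfig = ShiftCurveConfig()
    coloc: ColocConfig = ColocConfig()
    contact: ContactConfig = ContactConfig()
    track: TrackConfig = TrackConfig()
    msd: MsdConfig = MsdConfig()
    events: EventsConfig = EventsConfig()

    @field_validator("stages")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("stages must not be empty")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")
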