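"""Validated experiment configuration.

A flat ``key = value`` text format (``#`` comments) parsed into a pydantic
model; unknown keys are rejected by name.  One config describes a complete
simulate -> digitize -> metrics (-> dipole) experiment.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .emt_sim import SYSTEM_PROFILES

__all__ = ["ExperimentConfig", "InterferenceSpec", "parse_config", "load_config"]

FIXTURES = ("test_frame_9", "phantom_5", "head35", "eegcap32")


class InterferenceSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    x: float
    y: float
    z: float
    strength: float = Field(ge=0)
    decay_exponent: float = 3.0


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fixture: str = "head35"
    profile: str = "aurora"
    distances_mm: list[float] = Field(default_factory=lambda: [150.0])
    moving: bool = False
    seed: int = 0
    out_dir: str = "emtdig_out"
    dwell_time: float = 3.0
    cluster_radius_mm: float = 1.0
    cluster_min_count: int = 100
    max_error_index: float | None = None
    depth_mm: float = 0.0
    dipole_fit: bool = False
    interference: list[InterferenceSpec] = Field(default_factory=list)

    @field_validator("fixture")
    @classmethod
    def _check_fixture(cls, v):
        if v not in FIXTURES:
            raise ValueError(f"unknown fixture {v!r}; expected one of {FIXTURES}")
        return v

    @field_validator("profile")
    @classmethod
    def _check_profile(cls, v):
        if v not in SYSTEM_PROFILES:
            raise ValueError(
                f"unknown profile {v!r}; expected one of {tuple(SYSTEM_PROFILES)}"
            )
        return v


def parse_config(text: str) -> ExperimentConfig:
    """Parse flat ``key = value`` lines into an ExperimentConfig.

    List values are comma-separated.  Interference sources are given as
    ``interference = x,y,z,strength[,decay]`` lines (repeatable).
    """
    data: dict = {}
    interference: list[dict] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "interference":
            parts = [float(v) for v in value.split(",")]
            if len(parts) not in (4, 5):
                raise ValueError(
                    f"line {lineno}: interference needs x,y,z,strength[,decay]"
                )
            spec = dict(x=parts[0], y=parts[1], z=parts[2], strength=parts[3])
            if len(parts) == 5:
                spec["decay_exponent"] = parts[4]
            interference.append(spec)
        elif key == "distances_mm":
            data[key] = [float(v) for v in value.split(",")]
        elif key in ("moving", "dipole_fit"):
            data[key] = value.lower() in ("1", "true", "yes", "on")
        else:
            data[key] = value
    if interference:
        data["interference"] = interference
    return ExperimentConfig(**data)


def load_config(path) -> ExperimentConfig:
    return parse_config(Path(path).read_text())
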