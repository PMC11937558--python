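"""Validated configuration objects for enclosures, filters and event thresholds.

All thresholds carry the field defaults used throughout: distances in cm,
times in seconds, areas in m². Unknown keys are rejected so that a typo in a
YAML file fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class EnclosureConfig(BaseModel):
    """Geometry and occupancy of one turn-out enclosure.

    ``area_m2`` defaults to ``length_m * width_m`` but may be given
    independently, since published areas are sometimes rounded (e.g. a
    115 x 9.5 m paddock reported as 1093 m²).
    """

    model_config = ConfigDict(extra="forbid")

    length_m: float = Field(gt=0)
    width_m: float = Field(gt=0)
    area_m2: Optional[float] = Field(default=None, gt=0)
    n_horses: int = Field(ge=2)
    tracking_hours: float = Field(default=1.0, gt=0)
    feeder_channel: Optional[str] = None

    @model_validator(mode="after")
    def _fill_area(self) -> "EnclosureConfig":
        if self.area_m2 is None:
            self.area_m2 = self.length_m * self.width_m
        return self

    @property
    def max_theoretical_cm(self) -> float:
        """Enclosure diagonal in cm — the largest distance two animals can have."""
        return 100.0 * math.hypot(self.length_m, self.width_m)


class FilterConfig(BaseModel):
    """Thresholds of the four-step cleaning procedure."""

    model_config = ConfigDict(extra="forbid")

    min_cm: float = Field(default=5.0, gt=0)
    frozen_s: int = Field(default=10, gt=0)
    feeder_cm: float = Field(default=300.0, gt=0)


class EventConfig(BaseModel):
    """Thresholds of the agonistic approach/retreat detector.

    ``speed_floor_mode`` selects whether the 85 cm/s approach-speed floor is
    applied to the window-mean closing speed (default) or to every
    instantaneous step.
    """

    model_config = ConfigDict(extra="forbid")

    min_drop_cm: float = Field(default=100.0, gt=0)
    end_below_cm: float = Field(default=200.0, gt=0)
    window_s: int = Field(default=3, gt=0)
    min_speed_cm_s: float = Field(default=85.0, gt=0)
    max_speed_cm_s: float = Field(default=800.0, gt=0)
    retreat_lag_s: int = Field(default=3, ge=0)
    jitter_tol_cm: float = Field(default=1.0, ge=0)
    speed_floor_mode: str = Field(default="window", pattern="^(window|step)$")
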