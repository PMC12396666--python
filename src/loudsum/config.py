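"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import yaml

from .cohort import DEFAULT_GROUP_SIZES
from .metrics import MEANINGFUL_DIFFERENCE_DB, NH_BOUNDARY_DELTA_L40_DB
from .scaling import ScalingConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate→scale→fit→prescribe→analyze pipeline.

    Defaults reflect the emulated study conditions: 200 participants in
    four groups, a 22-trial shortened adaptive scaling run with 5 CU
    rating noise, gain comparisons on the 0.5/1/2/4 kHz x 50/65/80 dB SPL
    grid, a 5 dB meaningful-difference criterion and a 17.2 dB
    normal-hearing boundary for ΔL40.
    """

    seed: int = 0
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    trial_budget: int = 22
    phase1_step_db: float = 10.0
    start_level_db: float = 65.0
    noise_sd_cu: float = 5.0
    smoothing_halfwidth_db: float = 10.0
    comparison_frequencies_hz: Sequence[int] = (500, 1000, 2000, 4000)
    comparison_levels_db_spl: Sequence[int] = (50, 65, 80)
    meaningful_difference_db: float = MEANINGFUL_DIFFERENCE_DB
    nh_boundary_db: float = NH_BOUNDARY_DELTA_L40_DB

    def __post_init__(self) -> None:
        if self.meaningful_difference_db <= 0 or self.nh_boundary_db <= 0:
            raise ValueError("thresholds must be positive")
        if not self.comparison_frequencies_hz or not self.comparison_levels_db_spl:
            raise ValueError("comparison grids must be non-empty")

    @property
    def scaling(self) -> ScalingConfig:
        return ScalingConfig(trial_budget=self.trial_budget,
                             phase1_step_db=self.phase1_step_db,
                             start_level_db=self.start_level_db)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["group_sizes"] = dict(data["group_sizes"])
        data["comparison_frequencies_hz"] = list(self.comparison_frequencies_hz)
        data["comparison_levels_db_spl"] = list(self.comparison_levels_db_spl)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
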