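"""Simulated adaptive categorical loudness scaling and curve fitting.

Virtual listeners answer on the 11-category CU scale (0, 5, ..., 50); the
adaptive procedure first brackets the listener's dynamic range and then
distributes the remaining trial budget evenly over it, mirroring a
shortened clinical loudness-scaling run.  Fitted two-branch loudness
functions are recovered from trial logs by weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .loudness import CU_MAX, CU_MIN, CU_PIVOT, LoudnessFunction

__all__ = [
    "RESPONSE_CATEGORIES",
    "ScalingTrial",
    "VirtualListener",
    "ScalingConfig",
    "UnusableDynamicRangeError",
    "UnfittableDataError",
    "quantize_cu",
    "simulate_response",
    "run_adaptive_scaling",
    "fit_loudness_function",
]

#: The 11 response categories of the CU scale.
RESPONSE_CATEGORIES: tuple[int, ...] = tuple(range(0, 55, 5))

LEVEL_FLOOR_DB, LEVEL_CAP_DB = 0.0, 120.0


class UnusableDynamicRangeError(RuntimeError):
    """The listener saturates across the whole level range; no bracket found."""


class UnfittableDataError(ValueError):
    """Trial log carries too little information to fit a loudness function."""


@dataclass(frozen=True)
class ScalingTrial:
    """One presentation/response pair of an adaptive scaling run."""

    stimulus_id: str
    presentation_level: float  # dB SPL, post-amplification input scale
    response: int  # CU category, one of RESPONSE_CATEGORIES

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_CATEGORIES:
            raise ValueError(f"response {self.response} is not a CU category")
        if not LEVEL_FLOOR_DB <= self.presentation_level <= LEVEL_CAP_DB:
            raise ValueError(f"level {self.presentation_level} outside [0, 120] dB SPL")


@dataclass(frozen=True)
class VirtualListener:
    """Generative stand-in for a participant in the scaling simulation.

    ``functions`` maps stimulus ids to the listener's true broadband aided
    loudness functions; responses are the true CU plus Gaussian rating
    noise, quantized to the nearest category.
    """

    functions: Mapping[str, LoudnessFunction]
    response_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be non-negative")

    def true_function(self, stimulus_id: str) -> LoudnessFunction:
        try:
            return self.functions[stimulus_id]
        except KeyError:
            raise ValueError(f"listener has no function for stimulus {stimulus_id!r}") from None


@dataclass(frozen=True)
class ScalingConfig:
    """Parameters of the two-phase adaptive procedure.

    Phase 1 ascends from ``start_level_db`` in ``phase1_step_db`` steps
    until a response of at least 45 CU (or the 120 dB SPL cap), then
    descends until a response of at most 5 CU (or the floor); phase 2
    spends the remaining budget on levels evenly covering the bracketed
    range, presented in pseudo-random order.
    """

    trial_budget: int = 22
    phase1_step_db: float = 10.0
    start_level_db: float = 65.0

    def __post_init__(self) -> None:
        if self.trial_budget < 6:
            raise ValueError("trial_budget must be at least 6")
        if self.phase1_step_db <= 0:
            raise ValueError("phase1_step_db must be positive")


def quantize_cu(cu: float) -> int:
    """Round a continuous CU value to the nearest category (half-up)."""
    return int(np.clip(np.floor(cu / 5.0 + 0.5) * 5.0, CU_MIN, CU_MAX))


def simulate_response(
    listener: VirtualListener,
    stimulus_id: str,
    level: float,
    rng: np.random.Generator,
) -> int:
    """Simulate one categorical response at ``level`` dB SPL."""
    if not LEVEL_FLOOR_DB <= level <= LEVEL_CAP_DB:
        raise ValueError(f"level {level} outside [0, 120] dB SPL")
    cu = listener.true_function(stimulus_id).cu_at_level(level)
    if listener.response_noise_sd > 0:
        cu += rng.normal(0.0, listener.response_noise_sd)
    return quantize_cu(cu)


def run_adaptive_scaling(
    listener: VirtualListener,
    stimulus_id: str,
    config: ScalingConfig,
    rng: np.random.Generator,
) -> list[ScalingTrial]:
    """Run one simulated adaptive scaling measurement.

    Returns exactly ``config.trial_budget`` trials.  Raises
    :class:`UnusableDynamicRangeError` when no usable bracket exists
    (e.g. the listener is already near "too loud" at the level floor).
    """

    def present(level: float) -> ScalingTrial:
        level = float(np.clip(level, LEVEL_FLOOR_DB, LEVEL_CAP_DB))
        return ScalingTrial(stimulus_id, level, simulate_response(listener, stimulus_id, level, rng))

    trials: list[ScalingTrial] = []
    # Phase 1a: ascend until a "very loud or worse" rating or the cap.
    level = config.start_level_db
    while True:
        t = present(level)
        trials.append(t)
        if t.response >= 45 or level >= LEVEL_CAP_DB:
            break
        level = min(level + config.phase1_step_db, LEVEL_CAP_DB)
    upper = trials[-1].presentation_level
    # Phase 1b: descend until a "very soft or below" rating or the floor.
    level = config.start_level_db - config.phase1_step_db
    while level >= LEVEL_FLOOR_DB:
        t = present(level)
        trials.append(t)
        if t.response <= 5 or level <= LEVEL_FLOOR_DB:
            break
        level -= config.phase1_step_db
    lower = trials[-1].presentation_level if len(trials) > 1 else LEVEL_FLOOR_DB
    lower = min(lower, config.start_level_db)

    responses_so_far = [t.response for t in trials]
    saturated = min(responses_so_far) >= 45 or max(responses_so_far) <= 5
    if upper <= lower or saturated:
        raise UnusableDynamicRangeError(
            f"no dynamic-range bracket found for stimulus {stimulus_id!r}: "
            f"listener saturated across [{lower}, {upper}] dB SPL"
        )
    remaining = config.trial_budget - len(trials)
    if remaining < 2:
        raise UnusableDynamicRangeError(
            f"bracketing used {len(trials)} of {config.trial_budget} trials; "
            "no budget left for the coverage phase"
        )
    # Phase 2: even coverage of the bracketed range in pseudo-random order.
    grid = np.linspace(lower, upper, remaining)
    for level in grid[rng.permutation(remaining)]:
        trials.append(present(level))
    return trials


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_SLOPE_BOUNDS = (0.05, 5.0)
_CENSOR_WEIGHT = 0.5


def _two_branch_cu(params: np.ndarray, levels: np.ndarray) -> np.ndarray:
    l_cut, m_lo, m_hi = params
    x = levels - l_cut
    cu = np.where(x < 0.0, CU_PIVOT + m_lo * x, CU_PIVOT + m_hi * x)
    return np.clip(cu, CU_MIN, CU_MAX)


def fit_loudness_function(trials: Sequence[ScalingTrial]) -> LoudnessFunction:
    """Fit the two-branch loudness model to a trial log.

    Weighted least squares with smoothing off; saturated responses (0 or
    50 CU) are treated as censored and down-weighted.  Requires at least
    6 trials with at least 3 distinct non-saturated responses.
    """
    if len(trials) < 6:
        raise UnfittableDataError(f"only {len(trials)} trials; need at least 6")
    levels = np.array([t.presentation_level for t in trials], dtype=float)
    responses = np.array([t.response for t in trials], dtype=float)
    interior = (responses > CU_MIN) & (responses < CU_MAX)
    if len(np.unique(responses[interior])) < 3:
        raise UnfittableDataError(
            "fewer than 3 distinct non-saturated responses; loudness function "
            "is not identifiable"
        )
    weights = np.where(interior, 1.0, _CENSOR_WEIGHT)
    sqrt_w = np.sqrt(weights)

    # Initializer: line through the soft-side and loud-side response clouds.
    soft = responses <= CU_PIVOT
    loud = ~soft
    if soft.any() and loud.any():
        x1, y1 = np.median(levels[soft]), responses[soft].mean()
        x2, y2 = np.median(levels[loud]), responses[loud].mean()
    else:  # all on one side: anchor against the pivot guess
        x1, y1 = np.median(levels), responses.mean()
        x2, y2 = x1 + 15.0, min(y1 + 15.0, CU_MAX)
    slope0 = (y2 - y1) / (x2 - x1) if x2 != x1 else 0.5
    slope0 = float(np.clip(slope0, *_SLOPE_BOUNDS))
    l_cut0 = float(np.clip(x1 + (CU_PIVOT - y1) / slope0, LEVEL_FLOOR_DB, LEVEL_CAP_DB))

    def residuals(params: np.ndarray) -> np.ndarray:
        return sqrt_w * (_two_branch_cu(params, levels) - responses)

    lo = [LEVEL_FLOOR_DB - 30.0, _SLOPE_BOUNDS[0], _SLOPE_BOUNDS[0]]
    hi = [LEVEL_CAP_DB + 30.0, _SLOPE_BOUNDS[1], _SLOPE_BOUNDS[1]]
    result = least_squares(
        residuals,
        x0=[l_cut0, slope0, slope0],
        bounds=(lo, hi),
        method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    l_cut, m_lo, m_hi = result.x
    return LoudnessFunction(float(l_cut), float(m_lo), float(m_hi), smoothing_halfwidth=0.0)
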