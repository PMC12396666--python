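"""Categorical loudness functions and audiogram-based estimation.

Categorical loudness scaling rates loudness on a 0--50 categorical-unit
(CU) scale from "not heard" to "too loud"; 40 CU lies between "loud" and
"very loud".  This module implements the standard two-branch linear model
of the categorical loudness function (slopes in CU/dB pivoting at 25 CU),
normal-hearing (NH) reference functions for narrowband and broadband
binaural stimuli, and the estimation of hearing-impaired narrowband
loudness functions from air-conduction thresholds, which exhibits
recruitment: loudness grows abnormally fast above an elevated threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "AUDIOMETRIC_FREQUENCIES_HZ",
    "SaturatedCategoryError",
    "LoudnessFunction",
    "Audiogram",
    "TransducerTable",
    "EstimationCoefficients",
    "NarrowbandReferenceSet",
    "cu_at_level",
    "level_at_cu",
    "estimate_narrowband_function",
]

#: The 11 audiometric frequencies of a standard extended audiogram.
AUDIOMETRIC_FREQUENCIES_HZ: tuple[int, ...] = (
    125, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000,
)

#: Frequencies entering the pure-tone average (PTA).
PTA_FREQUENCIES_HZ: tuple[int, ...] = (500, 1000, 2000, 4000)

CU_MIN, CU_MAX, CU_PIVOT = 0.0, 50.0, 25.0


class SaturatedCategoryError(ValueError):
    """Inversion requested at a saturated category (0 or 50 CU plateau)."""


def _load_data(name: str) -> dict:
    with resources.files("loudsum.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class LoudnessFunction:
    """Two-branch categorical loudness function.

    Loudness in CU grows linearly with level at ``m_lo`` CU/dB below the
    pivot level ``l_cut`` (where the function passes 25 CU) and at ``m_hi``
    CU/dB above it, clipped to the 0--50 CU scale.  With
    ``smoothing_halfwidth`` > 0 the kink at the pivot is replaced by a
    quadratic Bezier transition over ``l_cut`` ± halfwidth, which keeps the
    function monotone and C1-continuous.

    Parameters
    ----------
    l_cut : float
        Pivot level in dB (SPL for broadband/aided stimuli).
    m_lo, m_hi : float
        Lower/upper branch slopes in CU/dB; both must be positive.
    smoothing_halfwidth : float, optional
        Half-width of the Bezier transition in dB (0 disables smoothing).
    """

    l_cut: float
    m_lo: float
    m_hi: float
    smoothing_halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if not (self.m_lo > 0 and self.m_hi > 0):
            raise ValueError("slopes m_lo and m_hi must be positive")
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be non-negative")

    # -- evaluation ----------------------------------------------------

    def cu_at_level(self, level):
        """Loudness in CU at ``level`` dB, clipped to [0, 50].

        Accepts scalars or arrays and is monotone non-decreasing in level.
        """
        level_arr = np.asarray(level, dtype=float)
        x = level_arr - self.l_cut
        cu = np.where(x < 0.0, CU_PIVOT + self.m_lo * x, CU_PIVOT + self.m_hi * x)
        h = self.smoothing_halfwidth
        if h > 0.0:
            # Quadratic Bezier with control points at the two branch points
            # and the pivot; the level coordinate is linear in t.
            t = np.clip((x + h) / (2.0 * h), 0.0, 1.0)
            cu0 = CU_PIVOT - self.m_lo * h
            cu2 = CU_PIVOT + self.m_hi * h
            bez = (1 - t) ** 2 * cu0 + 2 * t * (1 - t) * CU_PIVOT + t**2 * cu2
            cu = np.where(np.abs(x) < h, bez, cu)
        cu = np.clip(cu, CU_MIN, CU_MAX)
        return float(cu) if np.isscalar(level) or level_arr.ndim == 0 else cu

    def level_at_cu(self, cu: float) -> float:
        """Level in dB at which the function reaches ``cu`` CU.

        Exact inverse of :meth:`cu_at_level` for ``cu`` strictly inside
        (0, 50).  Raises :class:`SaturatedCategoryError` at or beyond the
        scale limits, where the clipped function is not invertible.
        """
        if not CU_MIN < cu < CU_MAX:
            raise SaturatedCategoryError(
                f"cannot invert loudness function at saturated category {cu} CU"
            )
        h = self.smoothing_halfwidth
        if h > 0.0:
            cu0 = CU_PIVOT - self.m_lo * h
            cu2 = CU_PIVOT + self.m_hi * h
            if cu0 < cu < cu2:
                # Invert the Bezier: a t^2 + b t + c = 0 with t in [0, 1].
                a = (self.m_hi - self.m_lo) * h
                b = 2.0 * self.m_lo * h
                c = cu0 - cu
                if abs(a) < 1e-12:
                    t = -c / b
                else:
                    disc = math.sqrt(b * b - 4.0 * a * c)
                    t = (-b + disc) / (2.0 * a)
                    if not -1e-9 <= t <= 1.0 + 1e-9:
                        t = (-b - disc) / (2.0 * a)
                return self.l_cut + (2.0 * t - 1.0) * h
        m = self.m_lo if cu < CU_PIVOT else self.m_hi
        return self.l_cut + (cu - CU_PIVOT) / m

    @property
    def l40(self) -> float:
        """Level at 40 CU — the upper loudness anchor used throughout."""
        return self.level_at_cu(40.0)

    def shifted(self, offset_db: float) -> "LoudnessFunction":
        """Return a copy translated along the level axis by ``offset_db``."""
        return replace(self, l_cut=self.l_cut + offset_db)


def cu_at_level(fn: LoudnessFunction, level):
    """Functional alias for :meth:`LoudnessFunction.cu_at_level`."""
    return fn.cu_at_level(level)


def level_at_cu(fn: LoudnessFunction, cu: float) -> float:
    """Functional alias for :meth:`LoudnessFunction.level_at_cu`."""
    return fn.level_at_cu(cu)


# ---------------------------------------------------------------------------
# audiograms and HL <-> SPL conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransducerTable:
    """RETSPL-style dB HL <-> dB SPL transfer table for one transducer dialect."""

    dialect: str
    retspl_db: Mapping[int, float]

    @classmethod
    def default(cls) -> "TransducerTable":
        data = _load_data("transducer_retspl.yaml")
        return cls(dialect=data["dialect"],
                   retspl_db={int(k): float(v) for k, v in data["retspl_db"].items()})

    def hl_to_spl(self, hl_db: float, frequency_hz: int) -> float:
        return hl_db + self._retspl(frequency_hz)

    def spl_to_hl(self, spl_db: float, frequency_hz: int) -> float:
        return spl_db - self._retspl(frequency_hz)

    def _retspl(self, frequency_hz: int) -> float:
        try:
            return self.retspl_db[int(frequency_hz)]
        except KeyError:
            raise ValueError(f"unsupported audiometric frequency {frequency_hz} Hz") from None


_BC_FREQUENCIES_HZ = (500, 1000, 2000, 4000)


@dataclass(frozen=True)
class Audiogram:
    """Per-ear air-conduction (and optional bone-conduction) thresholds.

    Air-conduction thresholds must be present for both ears at all 11
    audiometric frequencies and lie within [-10, 120] dB HL.
    """

    ac_db_hl: Mapping[str, Mapping[int, float]]
    bc_db_hl: Mapping[str, Mapping[int, float]] | None = None

    def __post_init__(self) -> None:
        for ear in ("L", "R"):
            if ear not in self.ac_db_hl:
                raise ValueError(f"air-conduction thresholds missing for ear {ear!r}")
            thr = self.ac_db_hl[ear]
            missing = [f for f in AUDIOMETRIC_FREQUENCIES_HZ if f not in thr]
            if missing:
                raise ValueError(f"ear {ear!r} missing thresholds at {missing} Hz")
            bad = {f: t for f, t in thr.items() if not -10.0 <= t <= 120.0}
            if bad:
                raise ValueError(f"ear {ear!r} thresholds outside [-10, 120] dB HL: {bad}")

    def threshold(self, ear: str, frequency_hz: int) -> float:
        return self.ac_db_hl[ear][int(frequency_hz)]

    def thresholds(self, ear: str) -> np.ndarray:
        return np.array([self.ac_db_hl[ear][f] for f in AUDIOMETRIC_FREQUENCIES_HZ])

    def pta(self, ear: str) -> float:
        """Pure-tone average over 0.5/1/2/4 kHz for one ear."""
        return float(np.mean([self.ac_db_hl[ear][f] for f in PTA_FREQUENCIES_HZ]))

    @property
    def better_ear_pta(self) -> float:
        return min(self.pta("L"), self.pta("R"))

    @property
    def interaural_pta_difference(self) -> float:
        return abs(self.pta("L") - self.pta("R"))


# ---------------------------------------------------------------------------
# normal-hearing references and impaired-function estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimationCoefficients:
    """Coefficients of the two-anchor audiogram-to-loudness-function model.

    The impaired narrowband function is constructed from two anchors:
    anchor A ("very soft", 2.5 CU) at ``threshold + very_soft_offset_db``
    (dB HL, converted to SPL) and anchor B ("too loud", 50 CU) at the NH
    top-anchor level plus ``top_recruitment_fraction`` times the threshold
    (partial recruitment at the top of the scale).  The 25-CU pivot sits at
    ``pivot_fraction`` of the way from anchor A to anchor B, and the branch
    slopes follow from the anchors.  At 0 dB HL the construction reduces to
    the NH reference itself.
    """

    very_soft_offset_db: float = 2.0
    top_recruitment_fraction: float = 0.25
    pivot_fraction: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 < self.pivot_fraction < 1.0:
            raise ValueError("pivot_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class NarrowbandReferenceSet:
    """NH reference loudness functions for narrowband and broadband stimuli.

    ``top_anchor_hl`` holds the per-frequency NH "too loud" (50 CU) anchor
    in dB HL; narrowband NH functions are built from it with the same
    two-anchor construction used for impaired functions (at 0 dB HL
    threshold).  ``broadband`` maps stimulus ids (``IFnoise``, ``UEN5``,
    ``UEN17``) to binaural broadband NH references in dB SPL; the packaged
    IFnoise reference reaches 40 CU at exactly 82.3 dB SPL.
    """

    top_anchor_hl: Mapping[int, float]
    broadband: Mapping[str, LoudnessFunction]
    transducer: TransducerTable = field(default_factory=TransducerTable.default)
    coefficients: EstimationCoefficients = field(default_factory=EstimationCoefficients)

    @classmethod
    def default(cls) -> "NarrowbandReferenceSet":
        data = _load_data("nh_references.yaml")
        nb = data["narrowband"]
        coeff = EstimationCoefficients(
            very_soft_offset_db=float(nb["very_soft_hl"]),
            pivot_fraction=float(nb["pivot_fraction"]),
        )
        broadband = {
            name: LoudnessFunction(float(p["l_cut"]), float(p["m_lo"]), float(p["m_hi"]))
            for name, p in data["broadband_binaural"].items()
        }
        return cls(
            top_anchor_hl={int(f): float(v) for f, v in nb["top_anchor_hl"].items()},
            broadband=broadband,
            coefficients=coeff,
        )

    def narrowband(self, frequency_hz: int, smoothing_halfwidth: float = 0.0) -> LoudnessFunction:
        """NH narrowband reference function at one audiometric frequency."""
        return estimate_narrowband_function(
            0.0, frequency_hz, self, smoothing_halfwidth=smoothing_halfwidth
        )

    def broadband_reference(self, stimulus_id: str) -> LoudnessFunction:
        try:
            return self.broadband[stimulus_id]
        except KeyError:
            raise ValueError(f"unknown broadband stimulus {stimulus_id!r}") from None


def estimate_narrowband_function(
    threshold_db_hl: float,
    frequency_hz: int,
    refs: NarrowbandReferenceSet,
    smoothing_halfwidth: float = 0.0,
) -> LoudnessFunction:
    """Estimate a narrowband loudness function from a hearing threshold.

    Implements the two-anchor recruitment construction described in
    :class:`EstimationCoefficients`: the bottom of the loudness scale rises
    with the threshold while the top anchor rises only partially, so the
    estimated function steepens with hearing loss (loudness recruitment).
    At 0 dB HL the NH reference for the frequency is returned.

    Parameters
    ----------
    threshold_db_hl : float
        Air-conduction threshold in dB HL, within [-10, 120].
    frequency_hz : int
        One of the 11 audiometric frequencies.
    refs : NarrowbandReferenceSet
        Reference set providing NH anchors, coefficients and the
        HL-to-SPL transducer table.
    smoothing_halfwidth : float, optional
        Smoothing half-width of the returned function in dB.
    """
    if not -10.0 <= threshold_db_hl <= 120.0:
        raise ValueError(f"threshold {threshold_db_hl} dB HL outside [-10, 120]")
    f = int(frequency_hz)
    if f not in AUDIOMETRIC_FREQUENCIES_HZ:
        raise ValueError(f"unsupported audiometric frequency {frequency_hz} Hz")
    c = refs.coefficients
    anchor_a_spl = refs.transducer.hl_to_spl(threshold_db_hl + c.very_soft_offset_db, f)
    top_nh_spl = refs.transducer.hl_to_spl(refs.top_anchor_hl[f], f)
    anchor_b_spl = top_nh_spl + c.top_recruitment_fraction * threshold_db_hl
    if anchor_b_spl <= anchor_a_spl:
        raise ValueError(
            f"degenerate dynamic range at {f} Hz for threshold {threshold_db_hl} dB HL"
        )
    l_cut = anchor_a_spl + c.pivot_fraction * (anchor_b_spl - anchor_a_spl)
    m_lo = (CU_PIVOT - 2.5) / (l_cut - anchor_a_spl)
    m_hi = (CU_MAX - CU_PIVOT) / (anchor_b_spl - l_cut)
    return LoudnessFunction(l_cut, m_lo, m_hi, smoothing_halfwidth)
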