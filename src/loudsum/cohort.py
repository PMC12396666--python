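"""Synthetic audiometric cohort generator.

Emulates a multi-centre study population of 200 participants in four
groups — 88 "New" and 72 "Experienced" hearing-aid users recruited at
hearing-aid professionals' facilities, 20 "Experimenter" users from a
research database, and 20 young normal-hearing (NH) listeners.  Each
record carries an audiogram (sloping loss around an N3-like mean
profile), tone and speech uncomfortable loudness levels (UCLs), a
hyperacusis questionnaire total score, age, a latent excess binaural
broadband loudness-summation value (ΔL40), and a virtual listener whose
aided broadband loudness function is the NH reference translated left by
that ΔL40.

Calibration targets (group ΔL40 means 13.2 / 13.2 / 8.1 dB, pooled
hearing-impaired 2.5/97.5 percentiles −12.4 / 36.1 dB, NH 95th
percentile 17.2 dB) are solved analytically from the configured
distribution family, not tuned on samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats

from .loudness import (
    AUDIOMETRIC_FREQUENCIES_HZ,
    PTA_FREQUENCIES_HZ,
    Audiogram,
    NarrowbandReferenceSet,
)
from .metrics import NH_BOUNDARY_DELTA_L40_DB
from .scaling import VirtualListener

__all__ = [
    "GROUPS",
    "HI_GROUPS",
    "DEFAULT_GROUP_SIZES",
    "DeltaL40Model",
    "CohortRecord",
    "calibrated_delta_l40_model",
    "sample_delta_l40",
    "sample_audiogram",
    "sample_covariates",
    "generate_cohort",
]

GROUPS: tuple[str, ...] = ("New", "Experienced", "Experimenter", "NH")
HI_GROUPS: tuple[str, ...] = ("New", "Experienced", "Experimenter")

#: Default group sizes (New, Experienced, Experimenter, NH).
DEFAULT_GROUP_SIZES: Mapping[str, int] = {
    "New": 88, "Experienced": 72, "Experimenter": 20, "NH": 20,
}

# Inclusion criteria for the hearing-impaired groups.
MIN_BETTER_EAR_PTA_DB = 30.0
MAX_INTERAURAL_PTA_DIFF_DB = 15.0
# NH admission: at most 15 dB HL at all but at most 2 frequencies.
NH_MAX_THRESHOLD_DB = 15.0
NH_MAX_EXCEEDANCES = 2

# ΔL40 calibration targets (dB).
_HAPF_MEAN = 13.2          # New and Experienced groups
_EXPERIMENTER_MEAN = 8.1
_POOLED_P025, _POOLED_P975 = -12.4, 36.1
_POOLED_WEIGHTS = (88, 72, 20)  # New : Experienced : Experimenter
#: Spread of the Experimenter group relative to the HAPF groups (design choice).
_EXPERIMENTER_SCALE_RATIO = 0.8

# Covariate model: linear-Gaussian couplings of UCL / IHS to centred ΔL40.
# Slopes solved from the target R² values given the residual SDs and the
# pooled HI ΔL40 SD of ~12.5 dB; the tone-UCL slope targets the R² of the
# *binaurally averaged* PTA UCL (8 draws, so the residual variance of the
# average is SD²/8).  See docs/methods.md.
_SPEECH_UCL_SLOPE = -0.32      # min monaural speech UCL, target R² ≈ 0.18
_SPEECH_UCL_BINAURAL_SLOPE = -0.205  # binaural speech UCL, target R² ≈ 0.10
_TONE_UCL_SLOPE = -0.0575      # tone UCLs, PTA-UCL average target R² ≈ 0.06
_IHS_SLOPE = 0.203             # IHS total score, target R² ≈ 0.03
_SPEECH_UCL_CORE_SD = 8.0
_SPEECH_UCL_EAR_SD = 2.0
_TONE_UCL_SD = 8.0
_IHS_MEAN, _IHS_SD = 30.0, 15.0

_AGE_BY_GROUP = {  # mean, sd in years
    "New": (70.9, 11.4),
    "Experienced": (72.7, 11.3),
    "Experimenter": (75.9, 12.3),
}
_NH_AGE_RANGE = (18.0, 25.0)

# Audiogram sampling around the N3-like anchor.
_GROUP_PROFILE_OFFSET = {"New": -5.0, "Experienced": 0.0, "Experimenter": 0.0}
_PROFILE_SHIFT_SD = 10.0   # common across-frequency level shift
_PROFILE_TILT_SD = 4.0     # slope jitter over the log-frequency axis
_PROFILE_LOCAL_SD = 3.0    # residual smooth per-frequency deviation
_EAR_DEVIATION_SD = 3.0    # per-ear deviation from the common profile
_NH_THRESHOLD_MEAN, _NH_THRESHOLD_SD = 5.0, 4.0


@dataclass(frozen=True)
class DeltaL40Model:
    """Calibrated per-group ΔL40 distributions.

    Hearing-impaired groups follow skew-normal laws (three parameters
    allow matching a mean and two mixture percentiles); the NH group is
    mean-zero Gaussian with its 95th percentile at the boundary value.
    """

    alpha: float
    xi_hapf: float
    omega_hapf: float
    xi_experimenter: float
    omega_experimenter: float
    nh_sd: float

    def distribution(self, group: str):
        """Frozen scipy distribution of ΔL40 for one group."""
        if group in ("New", "Experienced"):
            return stats.skewnorm(self.alpha, self.xi_hapf, self.omega_hapf)
        if group == "Experimenter":
            return stats.skewnorm(self.alpha, self.xi_experimenter, self.omega_experimenter)
        if group == "NH":
            return stats.norm(0.0, self.nh_sd)
        raise ValueError(f"unknown group {group!r}")

    def pooled_hi_cdf(self, x: float) -> float:
        """CDF of the pooled hearing-impaired mixture (88:72:20 weights)."""
        w = np.asarray(_POOLED_WEIGHTS, dtype=float)
        w /= w.sum()
        groups = ("New", "Experienced", "Experimenter")
        return float(sum(wi * self.distribution(g).cdf(x) for wi, g in zip(w, groups)))


@lru_cache(maxsize=1)
def calibrated_delta_l40_model() -> DeltaL40Model:
    """Solve the generator's ΔL40 distribution parameters from the targets.

    The HAPF (New/Experienced) and Experimenter skew-normals share the
    shape parameter and a fixed scale ratio; locations are pinned by the
    group means and the remaining two parameters (HAPF scale and shape)
    are solved so the pooled mixture hits both percentile targets.  The
    solve is deterministic, so the same parameters are obtained on every
    run.
    """
    sqrt_2_pi = np.sqrt(2.0 / np.pi)

    def build(omega1: float, alpha: float) -> DeltaL40Model:
        delta = alpha / np.sqrt(1.0 + alpha**2)
        xi1 = _HAPF_MEAN - omega1 * delta * sqrt_2_pi
        omega2 = _EXPERIMENTER_SCALE_RATIO * omega1
        xi2 = _EXPERIMENTER_MEAN - omega2 * delta * sqrt_2_pi
        nh_sd = NH_BOUNDARY_DELTA_L40_DB / stats.norm.ppf(0.95)
        return DeltaL40Model(alpha, xi1, omega1, xi2, omega2, nh_sd)

    def residual(v):
        model = build(*v)
        return [model.pooled_hi_cdf(_POOLED_P025) - 0.025,
                model.pooled_hi_cdf(_POOLED_P975) - 0.975]

    solution, info, ier, msg = optimize.fsolve(residual, [13.0, -1.5], full_output=True)
    if ier != 1:
        raise RuntimeError(f"ΔL40 calibration failed to converge: {msg}")
    return build(*solution)


def sample_delta_l40(
    group: str, rng: np.random.Generator, model: DeltaL40Model | None = None
) -> float:
    """Draw one latent ΔL40 value (dB) for a participant of ``group``."""
    model = model or calibrated_delta_l40_model()
    return float(model.distribution(group).rvs(random_state=rng))


# ---------------------------------------------------------------------------
# audiograms
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def n3_anchor() -> dict[int, float]:
    """The packaged N3-like mean threshold profile (dB HL per frequency)."""
    with resources.files("loudsum.data").joinpath("n3_anchor.yaml").open() as fh:
        data = yaml.safe_load(fh)
    return {int(f): float(v) for f, v in data["thresholds_db_hl"].items()}


def _nh_inclusion_ok(thresholds: np.ndarray) -> bool:
    return int(np.sum(thresholds > NH_MAX_THRESHOLD_DB)) <= NH_MAX_EXCEEDANCES


def sample_audiogram(
    group: str, rng: np.random.Generator, max_rejects: int = 1000
) -> Audiogram:
    """Draw one audiogram honouring the study's inclusion criteria.

    Hearing-impaired draws are a smooth perturbation of the N3-like
    anchor (common level shift, tilt over log-frequency, small local
    deviations, correlated ears) and are rejection-sampled until the
    better-ear PTA is at least 30 dB HL and the interaural PTA
    difference is at most 15 dB.  NH draws sit near 0 dB HL and satisfy
    the NH admission rule.
    """
    freqs = np.asarray(AUDIOMETRIC_FREQUENCIES_HZ, dtype=float)
    logf = (np.log10(freqs) - np.log10(freqs).mean()) / np.ptp(np.log10(freqs))
    for _ in range(max_rejects):
        if group == "NH":
            ears = {}
            for ear in ("L", "R"):
                thr = rng.normal(_NH_THRESHOLD_MEAN, _NH_THRESHOLD_SD, freqs.size)
                ears[ear] = np.clip(np.round(thr / 5.0) * 5.0, -10.0, 120.0)
            if _nh_inclusion_ok(ears["L"]) and _nh_inclusion_ok(ears["R"]):
                return Audiogram({e: dict(zip(AUDIOMETRIC_FREQUENCIES_HZ, map(float, t)))
                                  for e, t in ears.items()})
            continue
        if group not in _GROUP_PROFILE_OFFSET:
            raise ValueError(f"unknown group {group!r}")
        anchor = np.array([n3_anchor()[f] for f in AUDIOMETRIC_FREQUENCIES_HZ])
        shift = rng.normal(_GROUP_PROFILE_OFFSET[group], _PROFILE_SHIFT_SD)
        tilt = rng.normal(0.0, _PROFILE_TILT_SD)
        local = rng.normal(0.0, _PROFILE_LOCAL_SD, freqs.size)
        common = anchor + shift + tilt * logf + local
        ears = {}
        for ear in ("L", "R"):
            thr = common + rng.normal(0.0, _EAR_DEVIATION_SD, freqs.size)
            ears[ear] = np.clip(np.round(thr / 5.0) * 5.0, -10.0, 120.0)
        audiogram = Audiogram({e: dict(zip(AUDIOMETRIC_FREQUENCIES_HZ, map(float, t)))
                               for e, t in ears.items()})
        if (audiogram.better_ear_pta >= MIN_BETTER_EAR_PTA_DB
                and audiogram.interaural_pta_difference <= MAX_INTERAURAL_PTA_DIFF_DB):
            return audiogram
    raise RuntimeError(f"rejection budget exhausted sampling a {group!r} audiogram")


# ---------------------------------------------------------------------------
# covariates and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Covariates:
    """Per-participant covariates beyond the audiogram."""

    tone_ucl_db_hl: Mapping[str, Mapping[int, float]]  # ear -> freq -> UCL
    speech_ucl_left: float
    speech_ucl_right: float
    speech_ucl_binaural: float
    ihs_score: float
    age_years: float

    @property
    def speech_ucl_min_monaural(self) -> float:
        return min(self.speech_ucl_left, self.speech_ucl_right)

    @property
    def pta_ucl_db_hl(self) -> float:
        """Binaurally averaged PTA of the tone UCLs."""
        vals = [self.tone_ucl_db_hl[e][f] for e in ("L", "R") for f in PTA_FREQUENCIES_HZ]
        return float(np.mean(vals))


def sample_covariates(
    group: str, delta_l40: float, rng: np.random.Generator
) -> Covariates:
    """Draw UCLs, IHS score and age, given the latent ΔL40.

    Tone UCLs are Gaussian around 100 dB HL clipped to [80, 120]; speech
    UCLs carry a documented negative linear coupling to ΔL40 calibrated
    so the minimum monaural speech UCL explains about 18% of the ΔL40
    variance in the pooled hearing-impaired cohort (the strongest
    predictor), the binaural speech UCL about 10%, tone UCLs about 6%,
    and the IHS total score about 3%.
    """
    centred = delta_l40 - _HAPF_MEAN if group in HI_GROUPS else delta_l40
    tone: dict[str, dict[int, float]] = {}
    for ear in ("L", "R"):
        draws = 100.0 + _TONE_UCL_SLOPE * centred + rng.normal(0.0, _TONE_UCL_SD, 4)
        tone[ear] = {f: float(np.clip(v, 80.0, 120.0))
                     for f, v in zip(PTA_FREQUENCIES_HZ, draws)}
    core = 100.0 + _SPEECH_UCL_SLOPE * centred + rng.normal(0.0, _SPEECH_UCL_CORE_SD)
    left = float(np.clip(core + rng.normal(0.0, _SPEECH_UCL_EAR_SD), 80.0, 120.0))
    right = float(np.clip(core + rng.normal(0.0, _SPEECH_UCL_EAR_SD), 80.0, 120.0))
    binaural = float(np.clip(
        100.0 + _SPEECH_UCL_BINAURAL_SLOPE * centred + rng.normal(0.0, _SPEECH_UCL_CORE_SD),
        80.0, 120.0))
    ihs = float(max(_IHS_MEAN + _IHS_SLOPE * centred + rng.normal(0.0, _IHS_SD), 0.0))
    if group == "NH":
        age = float(rng.uniform(*_NH_AGE_RANGE))
    else:
        mean, sd = _AGE_BY_GROUP[group]
        age = float(np.clip(rng.normal(mean, sd), 18.0, 100.0))
    return Covariates(tone, left, right, binaural, ihs, age)


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic participant."""

    participant_id: str
    group: str
    audiogram: Audiogram
    covariates: Covariates
    latent_delta_l40: float
    listener: VirtualListener


def _make_listener(
    latent_delta_l40: float,
    refs: NarrowbandReferenceSet,
    response_noise_sd: float,
    smoothing_halfwidth: float,
) -> VirtualListener:
    """Aided IFnoise function = NH reference shifted left by the latent ΔL40."""
    ref = refs.broadband_reference("IFnoise")
    fn = replace(ref, l_cut=ref.l_cut - latent_delta_l40,
                 smoothing_halfwidth=smoothing_halfwidth)
    return VirtualListener({"IFnoise": fn}, response_noise_sd=response_noise_sd)


def generate_cohort(
    sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    response_noise_sd: float = 5.0,
    smoothing_halfwidth: float = 10.0,
    refs: NarrowbandReferenceSet | None = None,
) -> list[CohortRecord]:
    """Generate a fully seeded synthetic cohort.

    With the default sizes this yields 200 records (88 New, 72
    Experienced, 20 Experimenter, 20 NH).  Each record's virtual listener
    has an aided broadband loudness function with
    L40 = 82.3 − latent ΔL40 dB SPL.
    """
    sizes = dict(DEFAULT_GROUP_SIZES) if sizes is None else dict(sizes)
    unknown = set(sizes) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group(s) {sorted(unknown)}")
    if any(n < 0 for n in sizes.values()):
        raise ValueError("group sizes must be non-negative")
    refs = refs or NarrowbandReferenceSet.default()
    model = calibrated_delta_l40_model()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[CohortRecord] = []
    idx = 1
    for group in GROUPS:
        for _ in range(sizes.get(group, 0)):
            delta = sample_delta_l40(group, rng, model)
            audiogram = sample_audiogram(group, rng)
            cov = sample_covariates(group, delta, rng)
            listener = _make_listener(delta, refs, response_noise_sd, smoothing_halfwidth)
            records.append(CohortRecord(
                participant_id=f"P{idx:03d}",
                group=group,
                audiogram=audiogram,
                covariates=cov,
                latent_delta_l40=delta,
                listener=listener,
            ))
            idx += 1
    return records
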