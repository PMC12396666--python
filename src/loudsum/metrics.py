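"""Cohort-level statistics for the loudness-summation analysis.

ΔL40 (excess binaural broadband loudness summation), pure-tone averages,
prevalence beyond the normal-hearing boundary, predictor correlations and
multi-linear regression, Bonferroni-corrected pairwise group tests, and
the mean-unsigned-difference criterion between prescription rules.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .loudness import Audiogram
from .prescription import GainTable

__all__ = [
    "NH_REFERENCE_L40_DB_SPL",
    "NH_BOUNDARY_DELTA_L40_DB",
    "MEANINGFUL_DIFFERENCE_DB",
    "COMPARISON_FREQUENCIES_HZ",
    "delta_l40",
    "pta",
    "prevalence_excess",
    "GainDifference",
    "mean_unsigned_gain_difference",
    "correlation_r2",
    "adjusted_r2_multilinear",
    "group_ttests",
]

#: NH average level at 40 CU for the binaural broadband test signal (dB SPL).
NH_REFERENCE_L40_DB_SPL = 82.3

#: 95th percentile of NH ΔL40, used as the "beyond normal" boundary (dB).
NH_BOUNDARY_DELTA_L40_DB = 17.2

#: A-priori criterion for a meaningful gain-prescription difference (dB).
MEANINGFUL_DIFFERENCE_DB = 5.0

#: Frequencies at which prescription rules are compared.
COMPARISON_FREQUENCIES_HZ: tuple[int, ...] = (500, 1000, 2000, 4000)

COMPARISON_LEVELS_DB_SPL: tuple[int, ...] = (50, 65, 80)


def delta_l40(l40_ref: float, l40: float) -> float:
    """Excess binaural broadband loudness summation, ΔL40 = L40ref − L40.

    Positive values mean 40 CU is reached at lower input levels than the
    normal-hearing average — louder-than-normal perception of broadband
    binaural sounds after narrowband loudness normalization.
    """
    if not (np.isfinite(l40_ref) and np.isfinite(l40)):
        raise ValueError("L40 inputs must be finite")
    return float(l40_ref) - float(l40)


def pta(audiogram: Audiogram, ears: str = "both") -> float:
    """Pure-tone average over 0.5/1/2/4 kHz.

    ``ears`` is ``"L"``, ``"R"`` or ``"both"`` (unweighted mean of the
    two monaural PTAs).
    """
    if ears in ("L", "R"):
        return audiogram.pta(ears)
    if ears == "both":
        return 0.5 * (audiogram.pta("L") + audiogram.pta("R"))
    raise ValueError(f"ears must be 'L', 'R' or 'both', got {ears!r}")


def prevalence_excess(
    deltas: Iterable[float], boundary: float = NH_BOUNDARY_DELTA_L40_DB
) -> float:
    """Fraction of ΔL40 values strictly beyond the boundary.

    Equals one minus the empirical CDF at the boundary; raises on an
    empty input.
    """
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("prevalence of an empty collection is undefined")
    return float(np.mean(arr > boundary))


class GainDifference(NamedTuple):
    """Average unsigned gain difference between two rules, with criterion flag."""

    mean_unsigned_db: float
    meaningful: bool


def mean_unsigned_gain_difference(
    a: GainTable,
    b: GainTable,
    frequencies_hz: Sequence[float] = COMPARISON_FREQUENCIES_HZ,
    levels_db_spl: Sequence[float] = COMPARISON_LEVELS_DB_SPL,
    threshold_db: float = MEANINGFUL_DIFFERENCE_DB,
) -> GainDifference:
    """Mean |gain difference| over the comparison grid and both ears.

    Averages the unsigned difference over the 4 comparison frequencies,
    3 input levels and both ears (24 cells); the difference is deemed
    meaningful when the mean strictly exceeds the 5 dB criterion.
    Raises ``KeyError`` when either table does not cover the grid.
    """
    diffs = []
    for ear in ("L", "R"):
        if ear not in a.gains or ear not in b.gains:
            raise KeyError(f"both gain tables must cover ear {ear!r}")
        for f in frequencies_hz:
            for lv in levels_db_spl:
                diffs.append(abs(a.gain(ear, f, lv) - b.gain(ear, f, lv)))
    mean = float(np.mean(diffs))
    return GainDifference(mean, mean > threshold_db)


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r**2), float(p)


def adjusted_r2_multilinear(X, y) -> float:
    """Adjusted R² of an OLS fit of ``y`` on the predictor matrix ``X``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(np.std(X, axis=0) == 0.0):
        raise ValueError("constant predictor column")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared_adj)


def group_ttests(
    values: Sequence[float], groups: Sequence[str], correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups with Bonferroni correction.

    Returns a DataFrame with one row per group pair: ``group_a``,
    ``group_b``, ``t``, ``p_raw`` and ``p_corrected`` (raw p multiplied
    by the number of pairs, capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    by_group = {g: values[groups == g] for g in labels}
    for g, v in by_group.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    pairs = list(combinations(labels, 2))
    n_comparisons = len(pairs)
    rows = []
    for ga, gb in pairs:
        t, p = stats.ttest_ind(by_group[ga], by_group[gb], equal_var=False)
        p_corr = min(p * n_comparisons, 1.0) if correction == "bonferroni" else p
        rows.append((ga, gb, float(t), float(p), float(p_corr)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw", "p_corrected"])
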