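"""ΔL40, PTA, prevalence, gain-difference criterion and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loudsum import (
    adjusted_r2_multilinear,
    correlation_r2,
    delta_l40,
    group_ttests,
    mean_unsigned_gain_difference,
    prevalence_excess,
    pta,
)
from loudsum.prescription import GainTable

from conftest import flat_audiogram


class TestDeltaL40:
    @pytest.mark.parametrize(
        "ref, l40, expected",
        [(82.3, 69.3, 13.0), (82.3, 82.3, 0.0), (80.0, 100.0, -20.0)],
    )
    def test_worked_values(self, ref, l40, expected):
        assert delta_l40(ref, l40) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(-50.0, 150.0), b=st.floats(-50.0, 150.0))
    def test_antisymmetry(self, a, b):
        assert delta_l40(a, b) == pytest.approx(-delta_l40(b, a))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            delta_l40(float("nan"), 70.0)


class TestPTA:
    def test_unweighted_mean(self):
        from loudsum.loudness import AUDIOMETRIC_FREQUENCIES_HZ, Audiogram

        thr = {f: 0.0 for f in AUDIOMETRIC_FREQUENCIES_HZ}
        thr.update({500: 40.0, 1000: 45.0, 2000: 50.0, 4000: 55.0})
        audio = Audiogram({"L": thr, "R": {f: 0.0 for f in AUDIOMETRIC_FREQUENCIES_HZ}})
        assert pta(audio, "L") == pytest.approx(47.5)

    def test_binaural_average(self):
        assert pta(flat_audiogram(40.0), "both") == pytest.approx(40.0)
        from loudsum.loudness import AUDIOMETRIC_FREQUENCIES_HZ, Audiogram

        audio = Audiogram({
            "L": {f: 40.0 for f in AUDIOMETRIC_FREQUENCIES_HZ},
            "R": {f: 60.0 for f in AUDIOMETRIC_FREQUENCIES_HZ},
        })
        assert pta(audio, "both") == pytest.approx(50.0)


class TestPrevalence:
    def test_strict_boundary(self):
        assert prevalence_excess([10.0, 20.0], 17.2) == pytest.approx(0.5)
        assert prevalence_excess([17.2, 17.2, 17.2], 17.2) == 0.0
        with pytest.raises(ValueError):
            prevalence_excess([])

    def test_matches_analytic_exceedance_of_generator(self):
        """Empirical prevalence matches the calibrated distribution's tail."""
        from loudsum import calibrated_delta_l40_model

        model = calibrated_delta_l40_model()
        dist = model.distribution("Experienced")
        rng = np.random.default_rng(123)
        draws = dist.rvs(size=10_000, random_state=rng)
        analytic = 1.0 - dist.cdf(17.2)
        assert prevalence_excess(draws, 17.2) == pytest.approx(analytic, abs=0.02)

    def test_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10.0, 8.0, 500)
        b = 17.2
        assert prevalence_excess(vals, b) == pytest.approx(1.0 - np.mean(vals <= b))


def _random_table(rng) -> GainTable:
    freqs = np.array([500.0, 1000.0, 2000.0, 4000.0])
    levels = np.array([50.0, 65.0, 80.0])
    return GainTable(freqs, levels,
                     {e: rng.uniform(-20.0, 60.0, (4, 3)) for e in ("L", "R")})


class TestGainDifference:
    def test_identity_and_shift(self):
        rng = np.random.default_rng(0)
        a = _random_table(rng)
        same = mean_unsigned_gain_difference(a, a)
        assert same.mean_unsigned_db == 0.0 and not same.meaningful
        b = GainTable(a.frequencies_hz, a.levels_db_spl,
                      {e: g + 6.0 for e, g in a.gains.items()})
        shifted = mean_unsigned_gain_difference(a, b)
        assert shifted.mean_unsigned_db == pytest.approx(6.0)
        assert shifted.meaningful

    def test_unsigned_averaging(self):
        rng = np.random.default_rng(1)
        a = _random_table(rng)
        signs = np.ones((4, 3))
        signs.flat[::2] = -1.0
        b = GainTable(a.frequencies_hz, a.levels_db_spl,
                      {e: g + 4.0 * signs for e, g in a.gains.items()})
        diff = mean_unsigned_gain_difference(a, b)
        assert diff.mean_unsigned_db == pytest.approx(4.0)
        assert not diff.meaningful

    def test_metric_axioms(self):
        """Non-negativity, symmetry and the triangle inequality."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c = (_random_table(rng) for _ in range(3))
            dab = mean_unsigned_gain_difference(a, b).mean_unsigned_db
            dba = mean_unsigned_gain_difference(b, a).mean_unsigned_db
            dac = mean_unsigned_gain_difference(a, c).mean_unsigned_db
            dcb = mean_unsigned_gain_difference(c, b).mean_unsigned_db
            assert dab >= 0.0
            assert dab == pytest.approx(dba)
            assert dab <= dac + dcb + 1e-12

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        a = _random_table(rng)
        small = GainTable(np.array([500.0, 1000.0]), a.levels_db_spl,
                          {e: rng.uniform(0, 10, (2, 3)) for e in ("L", "R")})
        with pytest.raises(KeyError):
            mean_unsigned_gain_difference(a, small)


class TestRegressionAndTests:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r2, p = correlation_r2(x, 2.0 * x)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_null_r2_near_zero(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 10_000))
        r2, _ = correlation_r2(x, y)
        assert r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            adjusted_r2_multilinear(np.ones((10, 2)), np.arange(10.0))

    def test_adjusted_r2_penalizes_noise_predictors(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = 2.0 * x + rng.normal(size=200)
        X = np.column_stack([x, rng.normal(size=(200, 3))])
        adj = adjusted_r2_multilinear(X, y)
        r2_simple, _ = correlation_r2(x, y)
        assert 0.5 < adj <= r2_simple + 0.01

    def test_type_i_error_rate(self):
        """Equal-mean groups reject at ~alpha before correction."""
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(1000):
            a, b = rng.normal(size=(2, 20))
            table = group_ttests(np.concatenate([a, b]),
                                 ["g1"] * 20 + ["g2"] * 20)
            rejections += int(table["p_raw"].iloc[0] < 0.05)
        assert rejections / 1000 <= 0.075

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=30)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        table = group_ttests(values, groups)
        assert len(table) == 3
        assert np.all(table["p_corrected"] <= 1.0)
        assert np.all(table["p_corrected"] >= table["p_raw"] - 1e-12)
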