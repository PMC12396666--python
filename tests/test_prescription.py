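"""Gain prescription: normalization gains, broadband correction, CR, I/O."""

import numpy as np
import pytest
from loudsum import (
    IFnoiseSpectrum,
    broadband_correction,
    compression_ratio,
    export_gain_table,
    import_gain_table,
    narrowband_normalization_gains,
    stand_in_rule,
    trueloudness_gains,
)
from loudsum.prescription import (
    GainTableSchemaError,
    INPUT_LEVELS_DB_SPL,
    THIRD_OCTAVE_FREQUENCIES_HZ,
)

from conftest import grid_search_level


def test_spectrum_power_sums_to_overall_level():
    spec = IFnoiseSpectrum.default()
    for overall in (50.0, 65.0, 80.0):
        levels = spec.band_levels(overall)
        total = 10.0 * np.log10(np.sum(10.0 ** (levels / 10.0)))
        assert total == pytest.approx(overall, abs=1e-9)


class TestNarrowbandNormalization:
    def test_nh_audiogram_yields_zero_gain(self, nh_audiogram, refs):
        table = narrowband_normalization_gains(nh_audiogram, refs)
        for ear in ("L", "R"):
            assert np.max(np.abs(table.gains[ear])) <= 0.1

    def test_recruitment_forces_compression(self, flat60_audiogram, refs):
        """With recruitment, gain decreases as input level rises."""
        table = narrowband_normalization_gains(flat60_audiogram, refs)
        for ear in ("L", "R"):
            g = table.gains[ear]
            assert np.all(g[:, 1] < g[:, 0])  # 65 vs 50 dB SPL
            assert np.all(g[:, 2] < g[:, 1])  # 80 vs 65 dB SPL

    def test_matches_two_curve_grid_search(self, flat60_audiogram, refs):
        """Independent inversion of the two loudness curves, 1 kHz @ 65 dB."""
        from loudsum import estimate_narrowband_function

        spectrum = IFnoiseSpectrum.default()
        band_level = spectrum.band_level_at(1000.0, 65.0)
        nh = refs.narrowband(1000)
        hi = estimate_narrowband_function(60.0, 1000, refs)
        target_cu = nh.cu_at_level(band_level)
        expected_gain = grid_search_level(hi, target_cu) - band_level
        table = narrowband_normalization_gains(flat60_audiogram, refs)
        assert table.gain("L", 1000, 65) == pytest.approx(expected_gain, abs=0.1)


class TestBroadbandCorrection:
    def test_identity(self, ifnoise_ref):
        corr = broadband_correction(ifnoise_ref, ifnoise_ref)
        assert corr.offsets_db == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_translation(self, ifnoise_ref):
        corr = broadband_correction(ifnoise_ref.shifted(-10.0), ifnoise_ref)
        assert corr.offsets_db == pytest.approx((-10.0, -10.0, -10.0))

    def test_doubled_upper_slope_matches_grid_search(self, ifnoise_ref):
        from dataclasses import replace

        measured = replace(ifnoise_ref, m_hi=2.0 * ifnoise_ref.m_hi)
        corr = broadband_correction(measured, ifnoise_ref)
        for level, offset in zip(corr.levels_db_spl, corr.offsets_db):
            target_cu = ifnoise_ref.cu_at_level(level)
            expected = grid_search_level(measured, target_cu) - level
            assert offset == pytest.approx(expected, abs=0.01)


class TestTrueloudnessGains:
    def test_zero_correction_is_identity(self, flat60_audiogram, refs, ifnoise_ref):
        initial = narrowband_normalization_gains(flat60_audiogram, refs)
        corr = broadband_correction(ifnoise_ref, ifnoise_ref)
        final = trueloudness_gains(initial, corr)
        for ear in ("L", "R"):
            np.testing.assert_allclose(final.gains[ear], initial.gains[ear])

    def test_offsets_apply_uniformly_across_frequency(self, flat60_audiogram, refs):
        from loudsum.prescription import BroadbandCorrection

        initial = narrowband_normalization_gains(flat60_audiogram, refs)
        corr = BroadbandCorrection((50.0, 65.0, 80.0), (-10.0, -12.0, -15.0))
        final = trueloudness_gains(initial, corr)
        for ear in ("L", "R"):
            np.testing.assert_allclose(
                final.gains[ear] - initial.gains[ear],
                np.broadcast_to([-10.0, -12.0, -15.0], initial.gains[ear].shape),
            )

    def test_excess_summation_reduces_gain(self, flat60_audiogram, refs, ifnoise_ref):
        """ΔL40 = 20 dB: final gains fall strictly below the initial gains."""
        initial = narrowband_normalization_gains(flat60_audiogram, refs)
        measured = ifnoise_ref.shifted(-20.0)
        final = trueloudness_gains(initial, broadband_correction(measured, ifnoise_ref))
        for ear in ("L", "R"):
            assert np.all(final.gains[ear] < initial.gains[ear])

    def test_monotone_in_delta_l40(self, flat60_audiogram, refs, ifnoise_ref):
        """Final gains are non-increasing in the listener's ΔL40, cellwise."""
        initial = narrowband_normalization_gains(flat60_audiogram, refs)
        previous = None
        for delta in (-10.0, 0.0, 10.0, 20.0, 30.0):
            measured = ifnoise_ref.shifted(-delta)
            final = trueloudness_gains(initial, broadband_correction(measured, ifnoise_ref))
            stacked = np.concatenate([final.gains[e] for e in ("L", "R")])
            if previous is not None:
                assert np.all(stacked <= previous + 1e-9)
            previous = stacked

    def test_self_consistent_listener_needs_no_correction(self, flat60_audiogram, refs):
        """A listener whose aided broadband function is exactly normalized
        (no excess summation) gets a broadband correction of ~0 dB."""
        corr = broadband_correction(refs.broadband_reference("IFnoise"),
                                    refs.broadband_reference("IFnoise"))
        assert max(abs(o) for o in corr.offsets_db) <= 1.0


class TestCompressionRatio:
    @pytest.mark.parametrize(
        "g_lo, g_hi, l_lo, l_hi, expected, valid",
        [
            (30.0, 15.0, 50.0, 80.0, 2.0, True),
            (10.0, 10.0, 50.0, 80.0, 1.0, True),
            (0.0, 5.0, 50.0, 80.0, 30.0 / 35.0, True),
        ],
    )
    def test_worked_values(self, g_lo, g_hi, l_lo, l_hi, expected, valid):
        cr = compression_ratio(g_lo, g_hi, l_lo, l_hi)
        assert cr.value == pytest.approx(expected)
        assert cr.valid is valid

    def test_degenerate_cases_flagged(self):
        cr = compression_ratio(40.0, 10.0, 50.0, 80.0)  # denominator 0
        assert np.isinf(cr.value) and not cr.valid
        cr = compression_ratio(50.0, 10.0, 50.0, 80.0)  # negative denominator
        assert cr.value < 0 and not cr.valid
        with pytest.raises(ValueError):
            compression_ratio(0.0, 0.0, 80.0, 50.0)

    def test_agrees_with_direct_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            g_lo, g_hi = rng.uniform(-20.0, 60.0, 2)
            cr = compression_ratio(g_lo, g_hi, 50.0, 80.0)
            direct = 30.0 / (30.0 + g_hi - g_lo)
            assert cr.value == pytest.approx(direct, abs=1e-9)


class TestGainTableIO:
    def test_round_trip(self, flat60_audiogram, refs, tmp_path):
        table = narrowband_normalization_gains(flat60_audiogram, refs)
        path = tmp_path / "gains.csv"
        export_gain_table(table, path, participant_id="P001")
        back = import_gain_table(path)
        np.testing.assert_array_equal(back.frequencies_hz, table.frequencies_hz)
        for ear in ("L", "R"):
            np.testing.assert_array_equal(back.gains[ear], table.gains[ear])

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,ear,rule,frequency_hz,insertion_gain_db\n"
                        "P1,L,x,1000,10.0\n")
        with pytest.raises(GainTableSchemaError, match="level_db_spl"):
            import_gain_table(path)

    def test_bad_ear_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,ear,rule,frequency_hz,level_db_spl,insertion_gain_db\n"
            "P1,left,x,1000,65,10.0\n")
        with pytest.raises(GainTableSchemaError, match="ear"):
            import_gain_table(path)

    def test_stand_in_rule_identity_on_nh(self, nh_audiogram):
        table = stand_in_rule(nh_audiogram)
        for ear in ("L", "R"):
            np.testing.assert_array_equal(table.gains[ear], 0.0)
        assert table.metadata["rule"] == "standin-halfgain"

    def test_grid_covers_third_octaves(self, flat60_audiogram):
        table = stand_in_rule(flat60_audiogram)
        np.testing.assert_array_equal(table.frequencies_hz, THIRD_OCTAVE_FREQUENCIES_HZ)
        np.testing.assert_array_equal(table.levels_db_spl, INPUT_LEVELS_DB_SPL)
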