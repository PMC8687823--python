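"""Vitals extraction: peaks, heart rate, AC/DC decomposition, SpO2, temperature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalink.errors import (
    InsufficientSignalError,
    InvalidParameterError,
    StageError,
    UndefinedRatioError,
)
from vitalink.simulate import DualPPG, SimulationParams, synthesize_ppg
from vitalink.vitals import (
    CLASSIC,
    MAXIM,
    HeartRateCategory,
    PeakTrain,
    PPGComponents,
    classify_heart_rate,
    compute_ratio,
    detect_peaks,
    extract_components,
    get_calibration,
    heart_rate_from_peaks,
    process_window,
    quantize_temperature,
    spo2_definition,
    spo2_from_ratio,
)

FS = 100.0


class TestDetectPeaks:
    def test_pure_sinusoid_peak_count_and_spacing(self):
        t = np.arange(int(8 * FS)) / FS
        pk = detect_peaks(np.sin(2 * np.pi * 1.25 * t), FS)
        assert len(pk) == 10
        assert np.allclose(np.diff(pk.peak_times), 0.8, atol=0.01)

    def test_constant_signal_yields_empty_flagged_train(self):
        pk = detect_peaks(np.full(500, 3.0), FS)
        assert len(pk) == 0
        assert pk.flag == "no pulsatile activity"

    def test_simulated_beat_period_recovered(self):
        ppg = synthesize_ppg(SimulationParams(heart_rate_bpm=90, noise_sd=0))
        pk = detect_peaks(ppg.ir, FS)
        period = np.median(np.diff(pk.peak_times))
        assert abs(period - 60.0 / 90.0) <= 1.0 / FS

    def test_too_short_window_rejected(self):
        with pytest.raises(InsufficientSignalError):
            detect_peaks(np.sin(np.arange(100)), FS)  # 1 s only


class TestHeartRate:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ([0.0, 1.0, 2.0, 3.0], 60.0),
            ([0.0, 0.5, 1.0], 120.0),
            # one missed beat: median interval ignores the 2 s gap
            ([0.0, 0.8, 1.6, 3.6], 75.0),
        ],
    )
    def test_rate_from_intervals(self, times, expected):
        pk = PeakTrain(np.array(times), source_duration=5.0)
        assert heart_rate_from_peaks(pk) == pytest.approx(expected)

    def test_single_peak_insufficient(self):
        with pytest.raises(InsufficientSignalError):
            heart_rate_from_peaks(PeakTrain(np.array([1.0]), 5.0))

    @pytest.mark.parametrize(
        "hr, cat",
        [
            (75, HeartRateCategory.NORMAL),
            (59.9, HeartRateCategory.BELOW_NORMAL),
            (60, HeartRateCategory.NORMAL),
            (100, HeartRateCategory.NORMAL),
            (100.1, HeartRateCategory.ABOVE_NORMAL),
        ],
    )
    def test_classification_boundaries_inclusive(self, hr, cat):
        assert classify_heart_rate(hr) is cat

    @given(period=st.floats(0.35, 1.8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_uniform_peaks_give_exact_rate(self, period):
        times = np.arange(12) * period
        pk = PeakTrain(times, source_duration=times[-1] + 1)
        assert heart_rate_from_peaks(pk) == pytest.approx(60.0 / period)


class TestComponents:
    def test_known_offset_and_amplitude(self):
        t = np.arange(int(10 * FS)) / FS
        x = 2.0 + 0.5 * np.sin(2 * np.pi * t)
        comp = extract_components(DualPPG(FS, x, x))
        assert comp.dc_red == pytest.approx(2.0, abs=1e-3)
        assert comp.dc_ir == pytest.approx(2.0, abs=1e-3)
        assert comp.ac_red == pytest.approx(1.0, abs=1e-2)  # peak-to-peak
        assert compute_ratio(comp) == pytest.approx(1.0, abs=1e-6)

    def test_pure_dc_has_zero_ac(self):
        comp = extract_components(DualPPG(FS, np.full(500, 2.0), np.full(500, 2.0)))
        assert comp.ac_red == 0.0 and comp.ac_ir == 0.0

    def test_noiseless_simulator_ratios_recovered(self):
        p = SimulationParams(spo2_percent=92, noise_sd=0)
        comp = extract_components(synthesize_ppg(p))
        assert comp.ac_ir / comp.dc_ir == pytest.approx(
            p.perfusion_index_ir, rel=1e-3
        )
        assert compute_ratio(comp) == pytest.approx(p.truth_ratio, rel=1e-3)

    def test_per_beat_method_agrees_on_clean_signal(self):
        ppg = synthesize_ppg(SimulationParams(noise_sd=0))
        r_h = compute_ratio(extract_components(ppg, method="harmonic"))
        r_b = compute_ratio(extract_components(ppg, method="per_beat"))
        assert r_b == pytest.approx(r_h, rel=5e-3)


class TestRatioAndCalibration:
    def test_equal_normalized_amplitudes_give_unity(self):
        assert compute_ratio(PPGComponents(0.1, 2.0, 0.05, 1.0)) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        assert compute_ratio(PPGComponents(0.02, 1.0, 0.05, 1.0)) == pytest.approx(0.4)

    def test_red_channel_gain_cancels(self):
        a = compute_ratio(PPGComponents(0.02, 1.0, 0.05, 1.0))
        b = compute_ratio(PPGComponents(0.2, 10.0, 0.05, 1.0))
        assert a == pytest.approx(b)

    def test_zero_ir_ac_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            compute_ratio(PPGComponents(0.02, 1.0, 0.0, 1.0))

    @pytest.mark.parametrize(
        "r, cal, expected", [(1.0, CLASSIC, 85.0), (1.0, MAXIM, 87.0)]
    )
    def test_calibration_lines(self, r, cal, expected):
        est = spo2_from_ratio(r, cal)
        assert est.percent == expected and not est.clamped

    def test_clamp_flag_for_small_ratio(self):
        est = spo2_from_ratio(0.2, CLASSIC)
        assert est.percent == 100.0 and est.clamped
        assert est.raw_percent == pytest.approx(105.0)

    @given(r=st.floats(0.0, 5.0), name=st.sampled_from(["classic", "maxim"]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_always_physical_and_monotone(self, r, name):
        cal = get_calibration(name)
        est = spo2_from_ratio(r, cal)
        assert 0.0 <= est.percent <= 100.0
        # strictly decreasing before clamping
        assert cal.spo2(r + 0.01) < cal.spo2(r)

    @pytest.mark.parametrize(
        "hbo2, hb, expected", [(1, 1, 50.0), (1, 0, 100.0), (0, 1, 0.0)]
    )
    def test_saturation_definition(self, hbo2, hb, expected):
        assert spo2_definition(hbo2, hb) == expected

    def test_saturation_undefined_without_hemoglobin(self):
        with pytest.raises(InvalidParameterError):
            spo2_definition(0, 0)


class TestQuantizeTemperature:
    @pytest.mark.parametrize(
        "temp, expected",
        [
            (36.6875, 36.6875),          # already on the 12-bit grid
            (36.66, 36.6875),            # 586.56 steps -> nearest multiple is 587
            (0.03125, 0.0625),           # exact tie rounds away from zero
            (-0.03125, -0.0625),
        ],
    )
    def test_nearest_grid_point(self, temp, expected):
        assert quantize_temperature(temp, 0.0625) == pytest.approx(expected)

    @given(temp=st.floats(-50, 150), res=st.sampled_from([0.5, 0.25, 0.125, 0.0625]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_result_is_grid_multiple_within_half_step(self, temp, res):
        q = quantize_temperature(temp, res)
        assert abs(q / res - round(q / res)) < 1e-6
        assert abs(q - temp) <= res / 2 + 1e-9


class TestProcessWindow:
    def test_noiseless_window_recovers_truth(self):
        p = SimulationParams(heart_rate_bpm=75, spo2_percent=97, noise_sd=0)
        rec = process_window(synthesize_ppg(p), 36.66, MAXIM, "s1", 123.0)
        assert rec.heart_rate_bpm == pytest.approx(75, abs=2)
        assert rec.spo2_percent == pytest.approx(97, abs=1)
        assert rec.temperature_c == pytest.approx(36.6875)
        assert rec.subject_id == "s1" and rec.timestamp == 123.0

    def test_flat_signal_fails_in_heart_rate_stage(self):
        flat = DualPPG(FS, np.full(500, 1.0), np.full(500, 1.0))
        with pytest.raises(StageError) as err:
            process_window(flat, 36.6)
        assert err.value.stage == "heart_rate"

    def test_time_shift_leaves_estimates_unchanged(self):
        """Shifting a periodic noiseless window by whole beats is inert."""
        p = SimulationParams(heart_rate_bpm=60, duration_s=20, noise_sd=0)
        ppg = synthesize_ppg(p)
        shift = int(FS)  # exactly one 1 s beat
        shifted = DualPPG(FS, ppg.red[shift:], ppg.ir[shift:])
        a = process_window(ppg, 36.6)
        b = process_window(shifted, 36.6)
        assert b.heart_rate_bpm == pytest.approx(a.heart_rate_bpm, abs=0.05)
        assert b.spo2_percent == pytest.approx(a.spo2_percent, abs=0.05)
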