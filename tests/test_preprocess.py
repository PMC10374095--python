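"""Preprocessing chain: decimation, saturation zeroing, zero-phase band-pass,
artifact interpolation and the three-criterion channel-quality gate."""
import numpy as np
import pytest
from scipy import signal as sps

from slowwave.preprocess import (
    PreprocessConfig,
    apply_study_exclusion,
    bandpass_zero_phase,
    decimate_to_target,
    interpolate_artifacts,
    qc_from_metrics,
    run_preprocess,
    zero_saturated,
)
from slowwave.records import RawRecording
from slowwave.synth import ArtifactParams, generate_recording

CFG = PreprocessConfig()

# Published channel-quality worked example: 4 animals x 2 conditions x
# 4 channels of (% dropped, % artifact-interpolated, band power).
# Exactly three entries fail the (<20%, <20%, >1000) gate: channel 3 of
# animal 60-21 (both conditions) and of animal 87-21 (feeding only).
QC_WORKED_EXAMPLE = {
    ("58-21", "baseline"): {
        "dropped": [0.5, 0.5, 0.5, 0.5],
        "artifact": [2.0, 6.1, 1.9, 1.2],
        "power": [7.6e07, 8.3e08, 1.4e08, 1.2e08],
    },
    ("58-21", "feeding"): {
        "dropped": [18.3, 18.4, 17.9, 18.2],
        "artifact": [6.5, 2.8, 7.3, 5.4],
        "power": [2.0e08, 3.1e08, 4.0e08, 2.3e08],
    },
    ("60-21", "baseline"): {
        "dropped": [0.5, 0.5, 1.3, 0.5],
        "artifact": [3.0, 0.6, 51.2, 7.9],
        "power": [3.0e08, 7.2e07, 8.7e08, 6.7e08],
    },
    ("60-21", "feeding"): {
        "dropped": [4.4, 0.9, 1.6, 0.9],
        "artifact": [9.6, 4.8, 57.2, 8.6],
        "power": [4.6e08, 1.4e08, 8.7e08, 4.1e08],
    },
    ("87-21", "baseline"): {
        "dropped": [2.8, 0.7, 0.2, 0.1],
        "artifact": [2.2, 4.6, 3.1, 0.4],
        "power": [1.9e08, 9.1e07, 7.7e07, 2.0e07],
    },
    ("87-21", "feeding"): {
        "dropped": [2.6, 6.4, 3.9, 0.3],
        "artifact": [2.4, 12.7, 40.9, 0.9],
        "power": [1.2e08, 4.7e08, 9.8e08, 9.5e07],
    },
    ("103-21", "baseline"): {
        "dropped": [0.0, 0.0, 0.0, 0.0],
        "artifact": [1.4, 0.0, 0.0, 0.0],
        "power": [2.0e08, 1.5e08, 6.4e07, 4.9e07],
    },
    ("103-21", "feeding"): {
        "dropped": [0.0, 0.0, 0.0, 0.0],
        "artifact": [4.5, 0.0, 0.1, 0.0],
        "power": [5.7e08, 2.0e08, 1.4e08, 7.4e07],
    },
}
EXPECTED_QC_FAILURES = {
    ("60-21", "baseline", 3),
    ("60-21", "feeding", 3),
    ("87-21", "feeding", 3),
}


def make_rec(data, rate=2000.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1]:
        data = data.T
    return RawRecording(
        subject_id="t", condition="baseline", sample_rate_hz=rate,
        channels=[f"ch{i + 1}" for i in range(data.shape[1])],
        data=data, duration_s=data.shape[0] / rate,
    )


class TestDecimate:
    def test_factor_10_length(self):
        rec = make_rec(np.zeros(7_200_000), rate=2000.0)
        out = decimate_to_target(rec, CFG)
        assert out.n_samples == 720_000
        assert out.sample_rate_hz == 200.0

    def test_in_band_amplitude_preserved(self):
        t = np.arange(40_000) / 2000.0
        rec = make_rec(np.sin(2 * np.pi * 0.2 * t))
        out = decimate_to_target(rec, CFG)
        t200 = np.arange(out.n_samples) / 200.0
        ref = np.sin(2 * np.pi * 0.2 * t200)
        # compare away from filter edge effects
        sl = slice(500, -500)
        amp = np.abs(out.data[sl, 0]).max()
        assert amp == pytest.approx(np.abs(ref[sl]).max(), rel=0.01)

    def test_above_new_nyquist_suppressed(self):
        t = np.arange(40_000) / 2000.0
        x = np.sin(2 * np.pi * 150.0 * t)
        rec = make_rec(x)
        out = decimate_to_target(rec, CFG)
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(out.data[:, 0] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_non_integer_factor_errors(self):
        rec = make_rec(np.zeros(1999), rate=1999.0)
        with pytest.raises(ValueError, match="integer multiple"):
            decimate_to_target(rec, CFG)


class TestZeroSaturated:
    def test_constant_rail_all_dropped(self):
        out, frac = zero_saturated(np.full((100, 1), 200.0), CFG)
        assert np.all(out == 0.0)
        assert frac[0] == 1.0

    def test_in_range_untouched(self):
        x = np.random.default_rng(0).uniform(-1, 1, (100, 2))
        out, frac = zero_saturated(x, CFG)
        np.testing.assert_array_equal(out, x)
        assert np.all(frac == 0.0)

    def test_exact_count_ten_percent(self):
        x = np.zeros((120_000, 1))
        x[:12_000, 0] = 190.0
        out, frac = zero_saturated(x, CFG)
        assert frac[0] * 100 == pytest.approx(10.0)
        # brute-force recount of the bookkeeping
        assert (out != x).sum() == 12_000

    def test_boundary_value_is_dropped(self):
        out, frac = zero_saturated(np.array([[187.5], [187.49]]), CFG)
        assert out[0, 0] == 0.0 and out[1, 0] == 187.49

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-250, 250, (500, 3))
        once, f1 = zero_saturated(x, CFG)
        twice, f2 = zero_saturated(once, CFG)
        np.testing.assert_array_equal(once, twice)
        assert np.all(f2 == 0.0)


class TestBandpass:
    def test_dc_removed(self):
        x = np.full((120_000, 1), 5.0)
        y = bandpass_zero_phase(x, CFG, 200.0)
        trimmed = y[10_000:-10_000, 0]
        assert np.abs(trimmed).max() < 1e-3 * 5.0

    def test_in_band_zero_lag_and_gain(self):
        t = np.arange(120_000) / 200.0
        x = np.sin(2 * np.pi * 0.2 * t)
        y = bandpass_zero_phase(x[:, None], CFG, 200.0)[:, 0]
        sl = slice(20_000, -20_000)
        xc = sps.correlate(y[sl], x[sl], mode="full")
        lag = np.argmax(xc) - (len(x[sl]) - 1)
        assert lag == 0
        gain = np.sqrt(np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2))
        assert 0.9 <= gain <= 1.0

    @pytest.mark.parametrize("freq", [0.1, 0.2, 0.4, 0.6])
    def test_zero_phase_property_across_band(self, freq):
        t = np.arange(60_000) / 200.0
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_zero_phase(x[:, None], CFG, 200.0)[:, 0]
        sl = slice(10_000, -10_000)
        xc = sps.correlate(y[sl], x[sl], mode="full")
        assert np.argmax(xc) - (len(x[sl]) - 1) == 0

    def test_stopband_attenuation(self):
        t = np.arange(60_000) / 200.0
        x = np.sin(2 * np.pi * 5.0 * t)
        y = bandpass_zero_phase(x[:, None], CFG, 200.0)[:, 0]
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_band_outside_nyquist_errors(self):
        cfg = PreprocessConfig(band_high_hz=90.0)
        with pytest.raises(ValueError, match="Nyquist|outside"):
            bandpass_zero_phase(np.zeros((100, 1)), cfg, 100.0)


class TestInterpolateArtifacts:
    def test_in_range_unchanged(self):
        x = np.random.default_rng(0).uniform(-1.9, 1.9, (1000, 2))
        y, frac = interpolate_artifacts(x, CFG)
        np.testing.assert_array_equal(y, x)
        assert np.all(frac == 0.0)

    def test_interior_run_between_zeros(self):
        x = np.zeros((100, 1))
        x[50:55, 0] = 10.0
        y, frac = interpolate_artifacts(x, CFG)
        np.testing.assert_allclose(y[:, 0], 0.0)
        assert frac[0] == pytest.approx(5 / 100)

    def test_spike_on_ramp_follows_line(self):
        n = 1001
        ramp = np.linspace(0.0, 1.0, n)
        x = ramp.copy()
        x[500:503] = 10.0
        y, frac = interpolate_artifacts(x[:, None], CFG)
        np.testing.assert_allclose(y[:, 0], ramp, atol=1e-9)
        assert frac[0] == pytest.approx(3 / n)

    def test_edge_run_filled_with_nearest(self):
        x = np.zeros((50, 1))
        x[:5, 0] = 30.0
        x[5, 0] = 1.5
        y, _ = interpolate_artifacts(x, CFG)
        np.testing.assert_allclose(y[:5, 0], 1.5)

    def test_fully_saturated_channel_warns_not_crashes(self):
        x = np.full((100, 1), 10.0)
        with pytest.warns(UserWarning, match="all samples"):
            y, frac = interpolate_artifacts(x, CFG)
        assert frac[0] == 1.0
        np.testing.assert_allclose(y, 0.0)


class TestChannelQC:
    def test_worked_example_exact_flags(self):
        failures = set()
        for (animal, condition), row in QC_WORKED_EXAMPLE.items():
            for ch in range(4):
                qc = qc_from_metrics(
                    row["dropped"][ch], row["artifact"][ch], row["power"][ch], CFG
                )
                if not qc.passed:
                    failures.add((animal, condition, ch + 1))
        assert failures == EXPECTED_QC_FAILURES

    def test_high_artifact_channel_fails(self):
        assert not qc_from_metrics(1.3, 51.2, 8.7e08, CFG).passed

    def test_borderline_dropped_passes(self):
        assert qc_from_metrics(18.3, 6.5, 2.0e08, CFG).passed

    def test_zero_power_fails(self):
        assert not qc_from_metrics(0.0, 0.0, 0.0, CFG).passed

    def test_exactly_twenty_percent_fails(self):
        assert not qc_from_metrics(20.0, 0.0, 1e6, CFG).passed


class TestRunPreprocess:
    def quiet(self):
        return ArtifactParams(saturation_rate_per_hour=0, movement_rate_per_hour=0)

    def test_artifact_free_recording_all_retained(self):
        rec = generate_recording(
            "s01", "baseline", artifacts=self.quiet(), duration_s=120,
            sample_rate_hz=2000, seed=0,
        )
        clean = run_preprocess(rec)
        assert clean.retained_channels == ["ch1", "ch2", "ch3", "ch4"]
        for qc in clean.qc.values():
            assert qc.pct_dropped == 0.0
            assert qc.pct_interpolated == 0.0

    def test_channel3_artifacts_excluded(self):
        rec = generate_recording(
            "s01", "baseline", artifacts=self.quiet(), duration_s=120,
            sample_rate_hz=2000, seed=1,
        )
        rec.data[: rec.n_samples // 2, 2] = 187.5  # saturate half of channel 3
        clean = run_preprocess(rec)
        assert clean.retained_channels == ["ch1", "ch2", "ch4"]
        assert not clean.qc["ch3"].passed

    def test_rate_mismatch_fails_at_stage_one(self):
        rec = make_rec(np.zeros(1999), rate=1999.0)
        with pytest.raises(ValueError, match="stage 1"):
            run_preprocess(rec)

    def test_fingerprint_records_stage_order(self):
        rec = generate_recording(
            "s01", "baseline", artifacts=self.quiet(), duration_s=30,
            sample_rate_hz=200, seed=2,
        )
        clean = run_preprocess(rec)
        assert clean.fingerprint["stages"] == [
            "1:decimate",
            "2:zero_saturated",
            "3:bandpass_zero_phase",
            "4:interpolate_artifacts",
            "5:channel_qc",
        ]
        assert clean.fingerprint["config"]["band_low_hz"] == 0.05

    def test_duration_preserved(self):
        rec = generate_recording(
            "s01", "baseline", artifacts=self.quiet(), duration_s=60,
            sample_rate_hz=2000, seed=3,
        )
        clean = run_preprocess(rec)
        assert abs(clean.duration_s - 60.0) <= 1 / 200.0

    def test_study_exclusion_intersects(self):
        recs = []
        for s, cond in (("a", "baseline"), ("a", "feeding")):
            rec = generate_recording(
                s, cond, artifacts=self.quiet(), duration_s=60,
                sample_rate_hz=200, seed=4,
            )
            recs.append(rec)
        recs[1].data[:6000, 1] = 187.5  # channel 2 fails in one recording only
        cleans = [run_preprocess(r) for r in recs]
        apply_study_exclusion(cleans)
        for clean in cleans:
            assert clean.retained_channels == ["ch1", "ch3", "ch4"]
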