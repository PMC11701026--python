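"""Baseline correction, synchronization, integration and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanocal.simulate import SimConfig, ArtifactSpec, Peak, simulate_thermogram
from nanocal.thermogram import (
    BaselineFit,
    SyncConfig,
    Thermogram,
    ThermogramError,
    cumulative_heat,
    default_fit_windows,
    extract_features,
    fit_power_baseline,
    subtract_baseline,
    synchronize_group,
)


def flat_thermogram(power_W=1e-6, duration_h=10.0, dt_h=0.01, corrected=True):
    t = np.arange(dt_h, duration_h + dt_h / 2, dt_h)
    return Thermogram(t=t, p=np.full_like(t, power_W), corrected=corrected)


class TestIntegration:
    def test_constant_power(self):
        # 1 uW over 10 h = 0.036 J
        tg = flat_thermogram()
        _, cum = cumulative_heat(tg)
        assert cum[-1] == pytest.approx(1e-6 * (10.0 - 0.01) * 3600.0, rel=1e-12)

    def test_linear_ramp(self):
        t = np.linspace(0.0, 10.0, 1001)
        p = 2e-6 * t / 10.0
        tg = Thermogram(t=t, p=p, corrected=True)
        _, cum = cumulative_heat(tg)
        assert cum[-1] == pytest.approx(0.036, rel=1e-12)  # mean 1 uW x 10 h

    @given(
        st.lists(st.floats(-1e-6, 5e-6), min_size=3, max_size=12),
    )
    @settings(max_examples=40, deadline=None)
    def test_trapezoid_exact_for_piecewise_linear(self, powers):
        """Trapezoid equals the per-segment closed form for any node profile."""
        t = np.linspace(1.0, 4.0, len(powers))
        tg = Thermogram(t=t, p=np.array(powers), corrected=True)
        _, cum = cumulative_heat(tg)
        closed = sum(
            0.5 * (powers[i] + powers[i + 1]) * (t[i + 1] - t[i]) * 3600.0
            for i in range(len(powers) - 1)
        )
        assert cum[-1] == pytest.approx(closed, rel=1e-12, abs=1e-18)

    def test_additivity_over_adjacent_ranges(self):
        tg = simulate_thermogram(
            SimConfig(duration_h=30.0, dt_h=0.05, plateau_W=5e-8,
                      peaks=(Peak("gaussian", 1e-6, 15.0, 3.0),), seed=7,
                      noise_sd_W=1e-8)
        ).thermogram
        tg.corrected = True
        t = tg.t
        t1, t2, t3 = t[0], t[len(t) // 3], t[-1]
        _, left = cumulative_heat(tg, (t1, t2))
        _, right = cumulative_heat(tg, (t2, t3))
        _, full = cumulative_heat(tg, (t1, t3))
        assert left[-1] + right[-1] == pytest.approx(full[-1], rel=1e-12)

    def test_uncorrected_requires_override(self):
        tg = flat_thermogram(corrected=False)
        with pytest.raises(ThermogramError, match="not baseline-corrected"):
            cumulative_heat(tg)
        _, cum = cumulative_heat(tg, allow_uncorrected=True)
        assert cum[-1] > 0

    def test_too_few_points_rejected(self):
        tg = Thermogram(t=np.array([1.0, 2.0, 3.0]), p=np.ones(3), corrected=True,
                        mask=np.array([True, False, False]))
        with pytest.raises(ThermogramError, match="at least 2"):
            cumulative_heat(tg)


class TestPowerBaseline:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0.05, 50.0, 0.05)
        p = 5.0e-6 * t ** (-0.8) + 1e-7
        tg = Thermogram(t=t, p=p)
        fit = fit_power_baseline(tg)
        assert fit.a == pytest.approx(5.0e-6, rel=1e-6)
        assert fit.b == pytest.approx(-0.8, rel=1e-6)
        assert fit.c == pytest.approx(1e-7, rel=1e-6)
        assert fit.rmse < 1e-12

    def test_white_noise_fit_is_flat_at_the_mean(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.1, 100.0, 0.1)
        c_true, sigma = 2e-7, 1e-8
        tg = Thermogram(t=t, p=c_true + rng.normal(0, sigma, t.size))
        fit = fit_power_baseline(tg)
        baseline = fit(t)
        assert np.all(np.abs(baseline - c_true) < 3 * sigma)

    def test_fit_inside_generator_windows_tracks_true_artifact(self):
        cfg = SimConfig(
            duration_h=70.0, dt_h=0.02,
            artifact=ArtifactSpec(a=2e-6, b=-1.0, c=3e-8),
            peaks=(Peak("gaussian", 2.25e-6, 32.5, 2.0),),
            noise_sd_W=2e-8, seed=3,
        )
        exp = simulate_thermogram(cfg)
        tg = exp.thermogram
        windows = default_fit_windows(tg)
        fit = fit_power_baseline(tg, windows)
        for lo, hi in windows:
            tt = np.linspace(lo, hi, 50)
            true = cfg.artifact.evaluate(tt)
            assert np.all(np.abs(fit(tt) - true) <= 0.02 * np.abs(true) + 1e-9)

    def test_zero_time_in_window_rejected(self):
        t = np.arange(0.0, 10.0, 0.1)
        tg = Thermogram(t=t, p=np.ones_like(t))
        with pytest.raises(ThermogramError, match="t <= 0"):
            fit_power_baseline(tg, windows=[(0.0, 1.0), (9.0, 10.0)])

    def test_too_few_window_points_rejected(self):
        tg = flat_thermogram(duration_h=10.0, dt_h=1.0, corrected=False)
        with pytest.raises(ThermogramError, match="need >= 5"):
            fit_power_baseline(tg, windows=[(0.9, 1.1)])


class TestSubtractBaseline:
    def test_residuals_vanish_on_own_curve(self):
        t = np.arange(0.1, 20.0, 0.1)
        fit = BaselineFit(a=1e-6, b=-1.2, c=5e-8, fit_windows=[], rmse=0.0)
        tg = Thermogram(t=t, p=np.asarray(fit(t)))
        corrected = subtract_baseline(tg, fit)
        assert corrected.corrected
        assert np.max(np.abs(corrected.p)) < 1e-20

    def test_double_correction_rejected(self):
        t = np.arange(0.1, 5.0, 0.1)
        fit = BaselineFit(a=0.0, b=-1.0, c=0.0, fit_windows=[], rmse=0.0)
        tg = Thermogram(t=t, p=np.ones_like(t))
        once = subtract_baseline(tg, fit)
        with pytest.raises(ThermogramError, match="already"):
            subtract_baseline(once, fit)

    def test_full_exclusion_rejected(self):
        t = np.arange(0.1, 5.0, 0.1)
        fit = BaselineFit(a=0.0, b=-1.0, c=0.0, fit_windows=[], rmse=0.0)
        tg = Thermogram(t=t, p=np.ones_like(t))
        with pytest.raises(ThermogramError, match="mask out every sample"):
            subtract_baseline(tg, fit, exclusion=[(0.0, 10.0)])

    def test_raw_samples_preserved(self):
        t = np.arange(0.1, 5.0, 0.1)
        p = np.ones_like(t)
        tg = Thermogram(t=t, p=p.copy())
        fit = BaselineFit(a=0.0, b=-1.0, c=0.5, fit_windows=[], rmse=0.0)
        corrected = subtract_baseline(tg, fit, exclusion=[(0.0, 1.0)])
        # the original record is untouched; the correction is a new object
        assert np.array_equal(tg.p, p)
        assert tg.mask.all()
        assert len(corrected.p) == len(p)  # masked, not deleted


class TestSynchronize:
    def test_known_offset_alignment(self):
        cfg = SimConfig(duration_h=80.0, dt_h=0.05,
                        artifact=ArtifactSpec(a=1e-5, b=-2.0),
                        plateau_W=1e-7, noise_sd_W=2e-9, seed=5)
        base = simulate_thermogram(cfg).thermogram
        shifted = Thermogram(t=base.t + 0.5, p=base.p.copy(), label="offset")
        synced = synchronize_group([base, shifted])
        assert synced[0].cut_time_h == pytest.approx(synced[1].cut_time_h, abs=0.1)
        t0, p0 = synced[0].masked()
        t1, p1 = synced[1].masked()
        n = min(len(p0), len(p1))
        assert np.allclose(p0[:n], p1[:n], atol=1e-12)  # identical samples realign

    def test_plateau_recovered_after_cut(self):
        from nanocal.simulate import load_preset

        exp = simulate_thermogram(load_preset("unamended_demmo6", seed=21))
        (synced,) = synchronize_group([exp.thermogram])
        _, p = synced.masked()
        assert np.mean(p) == pytest.approx(1e-7, rel=0.05)

    def test_manual_cut_masks_before_time(self):
        tg = flat_thermogram(corrected=False)
        (synced,) = synchronize_group([tg], SyncConfig(manual_cut_h=1.0))
        t, _ = synced.masked()
        assert t.min() >= 1.0
        assert synced.cut_time_h == 1.0
        # raw data still there, only masked
        assert len(synced.t) == len(tg.t)

    def test_idempotent_on_synchronized_input(self):
        cfg = SimConfig(duration_h=60.0, dt_h=0.05,
                        artifact=ArtifactSpec(a=1e-5, b=-2.0),
                        plateau_W=1e-7, noise_sd_W=2e-9, seed=9)
        tg = simulate_thermogram(cfg).thermogram
        once = synchronize_group([tg])
        twice = synchronize_group(once)
        assert twice[0] is once[0]

    def test_never_settling_signal_instructs_manual_override(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.05, 20.0, 0.05)
        p = 1e-6 * t + rng.normal(0, 1e-10, t.size)  # relentless ramp
        tg = Thermogram(t=t, p=p)
        with pytest.raises(ThermogramError, match="manual"):
            synchronize_group([tg])

    def test_empty_group_rejected(self):
        with pytest.raises(ThermogramError):
            synchronize_group([])


class TestFeatures:
    def test_injected_peak_recovered(self):
        cfg = SimConfig(duration_h=70.0, dt_h=0.02,
                        peaks=(Peak("gaussian", 2.25e-6, 32.5, 2.0),),
                        noise_sd_W=2e-8, seed=13)
        tg = simulate_thermogram(cfg).thermogram
        tg.corrected = True  # no artifact injected
        fs = extract_features(tg)
        assert fs.peak_power_W == pytest.approx(2.25e-6, rel=0.05)
        assert abs(fs.peak_time_h - 32.5) < 1.0

    def test_decreasing_trace_peaks_at_first_point(self):
        t = np.arange(1.0, 10.0, 0.5)
        tg = Thermogram(t=t, p=1.0 / t, corrected=True)
        fs = extract_features(tg)
        assert fs.peak_time_h == t[0]

    def test_tie_break_earliest(self):
        t = np.arange(0.0, 5.0, 1.0)
        p = np.array([0.0, 2.0, 1.0, 2.0, 0.0])
        tg = Thermogram(t=t, p=p, corrected=True)
        assert extract_features(tg).peak_time_h == 1.0

    def test_all_masked_rejected(self):
        t = np.arange(1.0, 5.0, 1.0)
        tg = Thermogram(t=t, p=np.ones_like(t), corrected=True,
                        mask=np.zeros(t.size, dtype=bool))
        with pytest.raises(ThermogramError, match="masked"):
            extract_features(tg)

    def test_total_heat_equals_last_cumulative(self):
        tg = flat_thermogram()
        fs = extract_features(tg)
        assert fs.total_heat_J == fs.cumulative_J[-1]

    def test_ampule_lod_scales_with_volume(self):
        tg = flat_thermogram()
        assert tg.lod_W == pytest.approx(1.2e-9 * 2.0)
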