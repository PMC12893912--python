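"""Force reconstruction, cycle segmentation and swimming summaries."""

import math

import numpy as np
import pytest

from mesoswim import (
    CantileverModel,
    DeflectionTrace,
    ForceTrace,
    estimate_frequency,
    make_force_waveform,
    reconstruct_force,
    segment_cycles,
    simulate_tethered_trace,
    summarize,
    zero_baseline,
)
from mesoswim.calibration import InvalidInputError


def sinusoid_trace(f=8.0, amp=50e-6, fs=500.0, duration=6.0, offset=0.0):
    t = np.arange(int(duration * fs)) / fs
    return DeflectionTrace(sample_rate=fs,
                           deflection=offset + amp * np.sin(2 * np.pi * f * t))


class TestZeroBaseline:
    def test_subtracts_post_release_mean(self):
        fs = 500.0
        x = np.concatenate([np.full(2000, 30e-6), np.full(1000, 12e-6)])
        trace = DeflectionTrace(sample_rate=fs, deflection=x,
                                release_index=2000)
        out = zero_baseline(trace)
        assert out.deflection[:2000] == pytest.approx(18e-6)
        assert out.release_index == 2000

    def test_idempotent_on_zero_baseline(self):
        fs = 500.0
        x = np.concatenate([np.full(2000, 30e-6), np.zeros(1000)])
        trace = DeflectionTrace(sample_rate=fs, deflection=x,
                                release_index=2000)
        once = zero_baseline(trace)
        twice = zero_baseline(once)
        assert twice.deflection == pytest.approx(once.deflection, abs=1e-18)

    def test_missing_release_requires_explicit_baseline(self):
        trace = sinusoid_trace()
        with pytest.raises(InvalidInputError, match="baseline"):
            zero_baseline(trace)
        out = zero_baseline(trace, baseline=5e-6)
        assert out.deflection == pytest.approx(trace.deflection - 5e-6)

    def test_recovers_generator_offset(self, swim_cantilever):
        wf = make_force_waveform(0.8)
        trace = simulate_tethered_trace(
            wf, swim_cantilever, sample_rate=500.0, n_cycles=10,
            release_after=10, noise_sd=0.1e-6, seed=7,
            baseline_offset=20e-6, post_release_s=1.0)
        out = zero_baseline(trace)
        # recovered baseline: post-release samples should center on zero
        post = out.deflection[out.release_index + 100:]
        n = len(post)
        assert abs(np.mean(post)) < 3 * 0.1e-6 / math.sqrt(n) + 1e-9


class TestReconstructForce:
    def test_static_mode_constant_trace(self):
        trace = DeflectionTrace(sample_rate=100.0,
                                deflection=np.full(300, 10e-6))
        model = CantileverModel(k=0.01, b=3.55e-5, m_eff=1e-7)
        out = reconstruct_force(trace, model, mode="static")
        assert out.force == pytest.approx(0.1e-6, rel=1e-12)

    def test_drag_and_full_add_nothing_on_constant(self):
        trace = DeflectionTrace(sample_rate=100.0,
                                deflection=np.full(300, 10e-6))
        model = CantileverModel(k=0.01, b=3.55e-5, m_eff=1e-7)
        for mode in ("drag", "full"):
            out = reconstruct_force(trace, model, mode=mode)
            assert out.force[1:-1] == pytest.approx(0.1e-6, rel=1e-12)

    def test_drag_mode_matches_analytic_sinusoid(self):
        f, X, fs = 8.0, 50e-6, 1000.0
        w = 2 * np.pi * f
        trace = sinusoid_trace(f=f, amp=X, fs=fs)
        model = CantileverModel(k=0.01, b=3.55e-5, m_eff=1e-7)
        out = reconstruct_force(trace, model, mode="drag")
        t = trace.times
        analytic = model.k * X * np.sin(w * t) + model.b * X * w * np.cos(w * t)
        # central differences are O(dt^2): error bound ~ b*X*w^3*dt^2/6
        bound = 2 * model.b * X * w**3 / (6 * fs**2)
        assert np.max(np.abs(out.force[2:-2] - analytic[2:-2])) < bound

    def test_linearity_in_deflection(self):
        trace = sinusoid_trace()
        model = CantileverModel(k=0.01, b=3.55e-5, m_eff=1e-7)
        for mode in ("static", "drag", "full"):
            f1 = reconstruct_force(trace, model, mode=mode).force
            scaled = DeflectionTrace(sample_rate=trace.sample_rate,
                                     deflection=3.0 * trace.deflection)
            f3 = reconstruct_force(scaled, model, mode=mode).force
            assert f3 == pytest.approx(3.0 * f1, rel=1e-12)

    def test_auto_mode_threshold(self):
        trace = sinusoid_trace()
        soft = CantileverModel(k=0.01, b=3.55e-5, m_eff=1e-7)
        stiff = CantileverModel(k=0.03, b=3.55e-5, m_eff=1e-7)
        assert reconstruct_force(trace, soft, mode="auto").mode == "drag"
        assert reconstruct_force(trace, stiff, mode="auto").mode == "static"

    def test_ode_round_trip_error_decreases_with_rate(self, swim_cantilever):
        wf = make_force_waveform(1.0)
        errs = {}
        for fs in (250.0, 500.0, 1000.0):
            trace = simulate_tethered_trace(wf, swim_cantilever,
                                            sample_rate=fs, n_cycles=10)
            out = reconstruct_force(trace, swim_cantilever, mode="full")
            true = wf(trace.times)
            sl = slice(2, -2)
            errs[fs] = np.sqrt(np.mean((out.force[sl] - true[sl])**2)
                               / np.mean(true**2))
        assert errs[1000.0] < 0.02
        assert errs[1000.0] < errs[500.0] < errs[250.0]


class TestEstimateFrequency:
    def test_pure_sinusoid(self):
        trace = sinusoid_trace(f=8.0, fs=500.0, duration=6.0)
        f, se = estimate_frequency(trace)
        assert f == pytest.approx(8.0, abs=0.02)

    def test_prefers_fundamental_over_strong_harmonic(self):
        fs, dur = 500.0, 6.0
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * 8 * t) + 0.5 * np.sin(2 * np.pi * 16 * t)
        trace = DeflectionTrace(sample_rate=fs, deflection=x * 1e-6)
        f, _ = estimate_frequency(trace)
        assert f == pytest.approx(8.0, abs=0.1)

    def test_generator_frequency_law_recovered(self, swim_cantilever):
        # L = 0.52 mm -> f = 6.6 * 0.52**-0.35 = 8.30 Hz
        wf = make_force_waveform(0.52)
        assert wf.f == pytest.approx(8.30, abs=0.01)
        trace = simulate_tethered_trace(wf, swim_cantilever,
                                        sample_rate=500.0, n_cycles=20)
        force = reconstruct_force(trace, swim_cantilever)
        f, _ = estimate_frequency(force)
        assert f == pytest.approx(wf.f, rel=0.02)

    def test_flat_trace_has_no_periodicity(self):
        trace = DeflectionTrace(sample_rate=500.0, deflection=np.zeros(3000))
        from mesoswim.force import NoPeriodicityError

        with pytest.raises(NoPeriodicityError):
            estimate_frequency(trace)


class TestSegmentCycles:
    def test_offset_sinusoid_cycle_count(self):
        f, fs = 8.0, 500.0
        t = np.arange(int(48 / f * fs)) / fs
        force = ForceTrace(sample_rate=fs, mode="static",
                           force=1e-8 + 8e-8 * np.sin(2 * np.pi * f * t))
        bounds = segment_cycles(force, f)
        assert len(bounds) - 1 in (47, 48)

    def test_boundary_spacing_matches_period(self):
        f, fs = 8.0, 500.0
        t = np.arange(int(30 / f * fs)) / fs
        force = ForceTrace(sample_rate=fs, mode="static",
                           force=8e-8 * np.sin(2 * np.pi * f * t))
        bounds = segment_cycles(force, f)
        spacing = np.diff(bounds) / fs
        assert np.all(np.abs(spacing - 1 / f) < 0.05 / f)

    def test_synthetic_waveform_cycle_count(self, swim_cantilever):
        wf = make_force_waveform(1.0)
        trace = simulate_tethered_trace(wf, swim_cantilever,
                                        sample_rate=500.0, n_cycles=40,
                                        noise_sd=0.1e-6, seed=3)
        force = reconstruct_force(trace, swim_cantilever)
        bounds = segment_cycles(force, wf.f)
        assert abs((len(bounds) - 1) - 40) <= 1


class TestSummarize:
    def test_offset_sinusoid_closed_form(self):
        f, fs = 8.0, 1000.0
        t = np.arange(int(20 / f * fs)) / fs
        force = ForceTrace(sample_rate=fs, mode="static",
                           force=10e-9 + 80e-9 * np.sin(2 * np.pi * f * t))
        s = summarize(force, segment_cycles(force, f))
        assert s.F_p == pytest.approx(10e-9, rel=1e-3)
        assert s.F_peak == pytest.approx(160e-9, rel=1e-3)
        assert s.f == pytest.approx(8.0, rel=1e-3)

    def test_zero_mean_sinusoid(self):
        f, fs = 8.0, 1000.0
        t = np.arange(int(20 / f * fs)) / fs
        force = ForceTrace(sample_rate=fs, mode="static",
                           force=80e-9 * np.sin(2 * np.pi * f * t))
        s = summarize(force, segment_cycles(force, f))
        assert abs(s.F_p) < 1e-12
        assert s.F_peak == pytest.approx(160e-9, rel=1e-3)

    def test_generator_peak_ratio_recovered(self, swim_cantilever):
        # noiseless full-mode chain preserves the 16x peak-to-mean ratio
        for L in (0.5, 1.0, 1.4):
            wf = make_force_waveform(L)
            trace = simulate_tethered_trace(wf, swim_cantilever,
                                            sample_rate=1000.0, n_cycles=15)
            force = reconstruct_force(trace, swim_cantilever, mode="full")
            s = summarize(force, segment_cycles(force, wf.f))
            assert s.F_peak / s.F_p == pytest.approx(16.0, rel=0.03)

    def test_se_shrinks_as_root_n_cycles(self, swim_cantilever):
        wf = make_force_waveform(1.0)
        trace = simulate_tethered_trace(wf, swim_cantilever,
                                        sample_rate=500.0, n_cycles=130,
                                        noise_sd=0.3e-6, seed=11)
        force = reconstruct_force(trace, swim_cantilever)
        bounds = segment_cycles(force, wf.f)
        ns, ses = [], []
        for n in (8, 32, 128):
            s = summarize(force, bounds[:n + 1])
            ns.append(n)
            ses.append(s.se_Fp)
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)
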