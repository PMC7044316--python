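"""Delay-coupled phase-oscillator model: integrator, PLV, presets, sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tempotrack import (
    ModelParams,
    fit_to_behavior,
    frequency_sweep,
    mean_rotation_frequency,
    plv,
    preset,
    simulate,
)
from tempotrack.metrics import PerformanceCurve
from tempotrack.errors import DegenerateFitError, ParameterError


def _uncoupled(duration=10.0, **kw):
    base = dict(omega_s=1.0, omega_a=1.5, omega_m=1.7,
                k_as=0, k_am=0, k_ma=0, k_ms=0, d_a=0, d_m=0,
                duration=duration, burn_in=0.0)
    base.update(kw)
    return ModelParams(**base)


class TestSimulate:
    def test_free_rotation_advances_exactly_at_natural_frequency(self):
        p = _uncoupled()
        tr = simulate(p, seed=0)
        for th, w in ((tr.theta_s, 1.0), (tr.theta_a, 1.5), (tr.theta_m, 1.7)):
            steps = np.diff(th)
            assert np.allclose(steps, 2 * math.pi * w * p.dt, atol=1e-12)

    def test_stimulus_phase_exactly_linear(self):
        p = preset("auditory", "tracking", duration=50.0, burn_in=0.0)
        tr = simulate(p, seed=3)
        expect = tr.theta_s[0] + 2 * math.pi * p.omega_s * tr.t
        assert np.allclose(tr.theta_s, expect, atol=1e-9)

    def test_locking_condition_gives_unit_plv(self):
        # |2 pi (1.5 - 1.4)| = 0.63 rad/s < K = 2 rad/s: the pair locks
        p = _uncoupled(duration=1000.0, burn_in=100.0,
                       omega_s=1.5, omega_a=1.4, k_as=2.0)
        tr = simulate(p, seed=1)
        assert tr.plv_sa() == pytest.approx(1.0, abs=1e-6)

    def test_outside_locking_range_phase_slips(self):
        # |2 pi (1.5 - 1.0)| = 3.14 rad/s > K = 2 rad/s: no lock
        p = _uncoupled(duration=1000.0, burn_in=100.0,
                       omega_s=1.5, omega_a=1.0, k_as=2.0)
        tr = simulate(p, seed=1)
        assert tr.plv_sa() < 0.9

    def test_deterministic_given_seed(self):
        p = preset("visual", "passive", duration=20.0, burn_in=0.0)
        a = simulate(p, seed=42)
        b = simulate(p, seed=42)
        assert np.array_equal(a.theta_a, b.theta_a)
        assert np.array_equal(a.theta_m, b.theta_m)

    def test_identical_frequencies_plv_one_incommensurate_decays(self):
        same = _uncoupled(duration=100.0, omega_s=1.3, omega_a=1.3)
        tr = simulate(same, seed=0)
        assert tr.plv_sa() == pytest.approx(1.0, abs=1e-12)
        plvs = []
        for dur in (10.0, 100.0, 1000.0):
            p = _uncoupled(duration=dur, omega_s=1.0, omega_a=1.0 + math.sqrt(2) / 10)
            plvs.append(simulate(p, seed=0).plv_sa())
        assert plvs[0] > plvs[1] > plvs[2]

    def test_integration_converges_under_dt_halving(self):
        base = _uncoupled(duration=500.0, burn_in=100.0,
                          omega_s=1.5, omega_a=1.4, k_as=2.0)
        p1 = simulate(base, seed=0).plv_sa()
        p2 = simulate(replace(base, dt=base.dt / 2), seed=0).plv_sa()
        assert abs(p1 - p2) < 1e-3

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ModelParams(dt=0.0)
        with pytest.raises(ParameterError):
            ModelParams(duration=50.0, burn_in=100.0)
        with pytest.raises(ParameterError):
            ModelParams(k_as=-1.0)


class TestPLV:
    def test_constant_phase_difference_gives_one(self):
        x = np.linspace(0, 50, 500)
        assert plv(x, x - 0.7) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_phasor_cancellation(self):
        dphi = np.array([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
        assert plv(dphi, np.zeros(4)) == pytest.approx(0.0, abs=1e-12)

    def test_three_sample_complex_mean(self):
        # mean of {1, 1, i} = (2 + i)/3, modulus sqrt(5)/3
        dphi = np.array([0.0, 0.0, math.pi / 2])
        assert plv(dphi, np.zeros(3)) == pytest.approx(math.sqrt(5) / 3, abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ParameterError):
            plv([0.0], [0.0, 1.0])
        with pytest.raises(ParameterError):
            plv([], [])

    @given(offset=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_bounds_symmetry_and_offset_invariance(self, offset, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 20, size=50)
        y = rng.uniform(0, 20, size=50)
        v = plv(x, y)
        assert 0.0 <= v <= 1.0
        assert plv(y, x) == pytest.approx(v, abs=1e-12)
        assert plv(x + offset, y + offset) == pytest.approx(v, abs=1e-9)


class TestPresets:
    def test_auditory_tracking_printed_values(self):
        p = preset("auditory", "tracking")
        assert (p.k_am, p.k_ma, p.k_as, p.k_ms) == (10.0, 10.0, 10.0, 8.0)
        assert p.tau_ms == 0.1 and p.omega_a == 1.5
        assert (p.d_a, p.d_m) == (5.0, 10.0)
        assert p.tau_as == 0.1 and p.tau_am == 0.0 and p.tau_ma == 0.0

    def test_visual_passive_differs_in_attention_frequency_and_delay(self):
        aud = preset("auditory", "passive")
        vis = preset("visual", "passive")
        assert vis.omega_a == 0.7 and vis.tau_ms == 0.35 and vis.k_am == 2.0
        assert (vis.k_as, vis.k_ma, vis.k_ms) == (aud.k_as, aud.k_ma, aud.k_ms)

    def test_sessions_differ_only_in_motor_to_attention_coupling(self):
        a = preset("auditory", "passive")
        b = preset("auditory", "tracking")
        diff = {f for f in a.__dataclass_fields__
                if getattr(a, f) != getattr(b, f)}
        assert diff == {"k_am"}

    def test_printed_defaults(self):
        p = preset("auditory", "passive")
        assert p.dt == 0.025 and p.duration == 1e4 and p.omega_m == 1.7

    def test_unknown_labels_rejected(self):
        with pytest.raises(ParameterError):
            preset("tactile", "passive")
        with pytest.raises(ParameterError):
            preset("auditory", "resting")

    def test_delays_round_to_integer_steps(self):
        p = preset("visual", "passive")
        assert p.delay_steps(p.tau_ms) == 14  # 0.35 s at 25 ms
        assert preset("auditory", "passive").delay_steps(0.1) == 4


class TestFrequencySweep:
    def test_shape_and_determinism(self):
        p = preset("auditory", "passive", duration=20.0, burn_in=2.0)
        freqs = [0.5, 1.0, 1.5]
        a = frequency_sweep(p, freqs, 2, base_seed=9)
        b = frequency_sweep(p, freqs, 2, base_seed=9)
        assert a.plv_samples.shape == (3, 2)
        assert np.array_equal(a.plv_mean, b.plv_mean)

    def test_noiseless_resonant_drive_locks(self):
        p = preset("auditory", "passive", duration=300.0, burn_in=100.0,
                   d_a=0.0, d_m=0.0)
        curve = frequency_sweep(p, [1.5], 2, base_seed=0)
        assert curve.plv_mean[0] >= 0.99

    def test_empty_frequency_list_rejected(self):
        with pytest.raises(ParameterError):
            frequency_sweep(preset("auditory", "passive"), [], 2, base_seed=0)


class TestMeanRotationFrequency:
    def test_linear_phase(self):
        t = np.arange(0, 100) * 0.025
        assert mean_rotation_frequency(2 * math.pi * 1.7 * t, 0.025) == pytest.approx(1.7)

    def test_constant_phase_is_zero(self):
        assert mean_rotation_frequency(np.full(50, 2.2), 0.025) == 0.0

    def test_noisy_free_rotation_within_diffusion_error(self):
        p = _uncoupled(duration=1000.0, omega_m=1.7, d_m=10.0)
        tr = simulate(p, seed=5)
        est = mean_rotation_frequency(tr.theta_m, p.dt)
        tol = 3 * math.sqrt(2 * 10.0 / 1000.0) / (2 * math.pi)
        assert est == pytest.approx(1.7, abs=tol)

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            mean_rotation_frequency([1.0], 0.025)


class TestFitToBehavior:
    def _plv_curve(self, freqs, values):
        from tempotrack.oscillators import PLVCurve
        return PLVCurve(stim_freqs_hz=np.asarray(freqs, dtype=float),
                        plv_mean=np.asarray(values, dtype=float),
                        plv_sd=np.zeros(len(freqs)), n_realizations=1)

    def test_exact_affine_relation_gives_r2_one(self):
        freqs = [0.5, 1.0, 1.5, 2.0]
        plv_vals = np.array([0.2, 0.6, 0.9, 0.4])
        perf = PerformanceCurve(np.array(freqs), 0.5 + 0.4 * plv_vals,
                                np.full(4, 40))
        res = fit_to_behavior(self._plv_curve(freqs, plv_vals), perf)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(0.4, abs=1e-9)

    def test_constant_plv_is_degenerate(self):
        freqs = [0.5, 1.0, 1.5, 2.0]
        perf = PerformanceCurve(np.array(freqs), np.array([0.5, 0.6, 0.7, 0.8]),
                                np.full(4, 40))
        with pytest.raises(DegenerateFitError):
            fit_to_behavior(self._plv_curve(freqs, [0.5] * 4), perf)

    def test_grid_mismatch_rejected(self):
        perf = PerformanceCurve(np.array([0.5, 1.0, 1.5, 2.0]),
                                np.full(4, 0.7), np.full(4, 40))
        with pytest.raises(ParameterError):
            fit_to_behavior(self._plv_curve([0.5, 1.0, 1.5, 2.5],
                                            [0.1, 0.2, 0.3, 0.4]), perf)

    def test_independent_vectors_mean_r2_matches_theory(self, rng):
        # E[R^2] for one regressor on n = 8 independent points is 1/(n-1)
        # (permutation argument, distribution-free)
        freqs = np.arange(1.0, 9.0)
        r2 = []
        for _ in range(1000):
            x = rng.uniform(0.1, 0.9, size=8)
            y = rng.uniform(0.1, 0.9, size=8)
            perf = PerformanceCurve(freqs, y, np.full(8, 40))
            r2.append(fit_to_behavior(self._plv_curve(freqs, x), perf).r_squared)
        assert np.mean(r2) == pytest.approx(1 / 7, abs=0.02)
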