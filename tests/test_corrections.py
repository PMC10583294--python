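"""The three RF correction methods and the full correction pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flipcorr import (
    NonPhysicalCorrectionError,
    PulseScheme,
    apparent_params,
    cc_correct_amplitude,
    cc_correct_time,
    correct_experiment,
    cos_power_correct,
    iterative_correct,
    polarization_at,
    simulate_buildup,
    simulate_decay,
)


class TestCcTime:
    def test_zero_flip_angle_unchanged(self):
        assert cc_correct_time(31.0, 0.0, 2.0) == pytest.approx(31.0)

    def test_reference_buildup_inversion(self):
        # input 14.5 is a 3-digit rounding of the exact 14.45, hence ~1 %
        assert cc_correct_time(14.5, 25.0, 2.0) == pytest.approx(50.0, rel=0.02)

    def test_experimental_worked_example(self):
        # natural-abundance run: 4.7 deg / 1 s, uncorrected 47 s -> 56 s
        assert cc_correct_time(47.0, 4.7, 1.0) == pytest.approx(56.0, rel=0.02)

    @given(theta=st.floats(0.5, 60.0), TR=st.floats(0.2, 5.0))
    def test_round_trip_with_apparent_rate_is_exact(self, base, theta, TR):
        """cc_correct_time is the exact inverse of the apparent-rate formula."""
        app = apparent_params(base, theta, TR)
        assert cc_correct_time(app.tau, theta, TR) == pytest.approx(50.0, rel=1e-12)

    def test_non_physical_regime_raises(self):
        # aggressively pulsed decay: uncorrected tau' = 11 s at 24.7 deg / 1 s
        with pytest.raises(NonPhysicalCorrectionError):
            cc_correct_time(11.0, 24.7, 1.0)

    def test_failure_threshold_scales_with_rf_depletion(self):
        # RF depletion rate -ln(cos)/TR just below 1/tau' is still fine
        theta, TR = 20.0, 0.5
        rate = -math.log(math.cos(math.radians(theta))) / TR
        assert cc_correct_time(1.0 / (rate * 1.01), theta, TR) > 0
        with pytest.raises(NonPhysicalCorrectionError):
            cc_correct_time(1.0 / (rate * 0.99), theta, TR)


class TestCcAmplitude:
    def test_enhancement_worked_examples(self):
        # DNP-juice run 7.1 deg / 1 s: eps' 106, tau' 24 s -> eps ~ 130
        tau = cc_correct_time(24.0, 7.1, 1.0)
        assert cc_correct_amplitude(106.0, 24.0, tau) == pytest.approx(130.0, rel=0.02)
        # natural-abundance run 4.7 deg / 1 s: eps' 149, tau' 47 s -> eps ~ 177
        tau = cc_correct_time(47.0, 4.7, 1.0)
        assert cc_correct_amplitude(149.0, 47.0, tau) == pytest.approx(177.0, rel=0.02)

    def test_identity_when_tau_unchanged(self):
        assert cc_correct_amplitude(0.29, 31.0, 31.0) == pytest.approx(0.29)

    def test_amplitude_error_grows_with_flip_angle(self, base):
        """The tau/tau' amplitude rescaling is approximate; its noiseless
        recovery error grows from ~0.4 % at 7 deg to several % at 25 deg."""
        errors = {}
        for theta in (7.0, 12.5, 25.0):
            app = apparent_params(base, theta, 2.0)
            tau_cc = cc_correct_time(app.tau, theta, 2.0)
            P0_cc = cc_correct_amplitude(app.P0, app.tau, tau_cc)
            errors[theta] = abs(P0_cc / 0.3 - 1.0)
        assert errors[7.0] < 0.006
        assert 0.005 < errors[12.5] < 0.02
        assert 0.02 < errors[25.0] < 0.10
        assert errors[7.0] < errors[12.5] < errors[25.0]


class TestIterative:
    def test_zero_flip_angle_is_identity(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=0.0, TR=2.0, n_pulses=80))
        res = iterative_correct(ts, rate_sum=0.02)
        np.testing.assert_allclose(res.series.signals, ts.signals, rtol=1e-12)

    def test_first_point_is_kept_exact(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=25.0, TR=2.0, n_pulses=60))
        res = iterative_correct(ts, rate_sum=0.02)
        assert res.series.signals[0] == ts.signals[0]

    def test_noiseless_buildup_series_matches_rf_free_curve(self, base):
        """At 37 deg / TR 2 the reconstructed points track the pulse-free
        closed form within 2 % everywhere."""
        ts = simulate_buildup(base, PulseScheme(theta=37.0, TR=2.0, n_pulses=150))
        res = iterative_correct(ts, rate_sum=0.02)
        truth = polarization_at(ts.times, base)
        np.testing.assert_allclose(res.series.signals, truth, rtol=0.02)

    @pytest.mark.parametrize("theta", [2.5, 7.0, 12.5, 25.0, 37.0])
    @pytest.mark.parametrize("TR", [0.5, 1.0, 2.0])
    def test_noiseless_parameter_recovery(self, base, theta, TR):
        ts = simulate_buildup(base, PulseScheme(theta=theta, TR=TR))
        res = correct_experiment(ts, method="iterative")
        assert res.tau == pytest.approx(50.0, rel=0.02)
        assert res.P0 == pytest.approx(0.3, rel=0.02)

    def test_decay_agrees_with_cos_power(self):
        kR = 1.0 / 173.0
        ts = simulate_decay(kR, PulseScheme(theta=7.0, TR=1.0, n_pulses=200), P_init=0.3)
        it = correct_experiment(ts, method="iterative")
        cp = cos_power_correct(ts)
        keep = cp.series.signals > 1e-6
        np.testing.assert_allclose(
            it.series.signals[keep], cp.series.signals[keep], rtol=5e-3
        )
        assert it.tau == pytest.approx(cp.tau, rel=5e-3)

    def test_non_uniform_spacing_rejected(self, base):
        from dataclasses import replace

        ts = simulate_buildup(base, PulseScheme(theta=7.0, TR=2.0, n_pulses=20))
        t = ts.times.copy()
        t[5] += 0.3
        crooked = replace(ts, times=t)
        with pytest.raises(ValueError, match="uniformly spaced"):
            iterative_correct(crooked, rate_sum=0.02)

    def test_iterative_beats_cc_amplitude_at_large_flip_angle(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=25.0, TR=2.0))
        it = correct_experiment(ts, method="iterative")
        cc = correct_experiment(ts, method="cc")
        assert abs(it.P0 - 0.3) < abs(cc.P0 - 0.3)


class TestCosPower:
    def test_zero_flip_angle_identity(self):
        ts = simulate_decay(0.01, PulseScheme(theta=0.0, TR=2.0, n_pulses=40), P_init=0.3)
        res = cos_power_correct(ts)
        np.testing.assert_allclose(res.series.signals, ts.signals, rtol=1e-12)

    @pytest.mark.parametrize("theta", [2.5, 7.0, 12.5, 25.0, 37.0])
    def test_exact_on_noiseless_pulsed_decay(self, theta):
        """The correction exactly restores P_init*exp(-kR*t) point by point."""
        kR = 0.005
        ts = simulate_decay(kR, PulseScheme(theta=theta, TR=2.0, n_pulses=80), P_init=0.3)
        res = cos_power_correct(ts)
        np.testing.assert_allclose(
            res.series.signals, 0.3 * np.exp(-kR * ts.times), rtol=1e-10
        )
        assert res.tau == pytest.approx(1.0 / kR, rel=1e-6)

    def test_refused_on_buildups(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=7.0, TR=2.0, n_pulses=40))
        with pytest.raises(ValueError, match="only applicable to decays"):
            cos_power_correct(ts)

    def test_noise_amplification_exceeds_fit_based_methods(self):
        """Late-time noise blown up by 1/cos^(n-1) makes the cos-power tau
        estimate more variable than the iterative one."""
        from flipcorr.studies import child_rng

        kR, theta = 1.0 / 173.0, 12.0
        taus_cp, taus_it = [], []
        for rep in range(40):
            ts = simulate_decay(
                kR,
                PulseScheme(theta=theta, TR=1.0, n_pulses=400),
                P_init=0.3,
                noise_sigma=3.2e-4,
                seed=child_rng(21, rep),
            )
            taus_cp.append(cos_power_correct(ts).tau)
            taus_it.append(correct_experiment(ts, method="iterative").tau)
        assert np.std(taus_cp) > np.std(taus_it)


class TestCorrectExperiment:
    def test_zero_flip_angle_identity(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=0.0, TR=2.0, n_pulses=100))
        res = correct_experiment(ts, method="iterative")
        assert res.tau == pytest.approx(res.uncorrected.tau_hat, rel=1e-9)
        assert res.P0 == pytest.approx(res.uncorrected.P0_hat, rel=1e-9)

    def test_noiseless_25deg_recovery(self, base):
        ts = simulate_buildup(base, PulseScheme(theta=25.0, TR=2.0))
        res = correct_experiment(ts, method="iterative")
        assert res.tau == pytest.approx(50.0, rel=0.02)
        assert res.P0 == pytest.approx(0.3, rel=0.02)

    def test_noisy_25deg_recovery_within_10_percent(self, base):
        app = apparent_params(base, 25.0, 2.0)
        sigma = math.sin(math.radians(25.0)) * app.P0 / 40.0  # SNR ~ 40
        ts = simulate_buildup(base, PulseScheme(theta=25.0, TR=2.0), noise_sigma=sigma, seed=9)
        res = correct_experiment(ts, method="iterative")
        assert res.tau == pytest.approx(50.0, rel=0.10)
        assert res.P0 == pytest.approx(0.3, rel=0.10)

    def test_corrected_tau_never_below_apparent(self, base):
        for theta in (2.5, 12.5, 25.0):
            ts = simulate_buildup(base, PulseScheme(theta=theta, TR=2.0))
            res = correct_experiment(ts, method="iterative")
            assert res.tau >= res.uncorrected.tau_hat
            assert res.P0 >= res.uncorrected.P0_hat

    def test_outer_rate_loop_converges(self, base):
        """The optional rate fixed-point loop settles, but the single CC
        pass (whose rate is exact on noiseless data) is more accurate."""
        ts = simulate_buildup(base, PulseScheme(theta=25.0, TR=2.0))
        res = correct_experiment(ts, method="iterative", max_iter=20, tol=1e-3)
        assert res.converged
        assert res.n_iterations >= 2
        assert res.tau == pytest.approx(50.0, rel=0.10)
        single = correct_experiment(ts, method="iterative")
        assert abs(single.tau - 50.0) < abs(res.tau - 50.0)

    def test_cc_pipeline_flags_non_physical_decay(self):
        """A decay dominated by RF depletion (sin(theta)/TR >> kR) whose
        apparent rate is overestimated -- here through a miscalibrated flip
        angle, experimentally through fit noise -- yields a flagged,
        divergent CC result rather than a crash."""
        ts = simulate_decay(
            1.0 / 500.0, PulseScheme(theta=24.7, TR=1.0, n_pulses=60), P_init=0.3
        )
        res = correct_experiment(ts, theta=26.0, method="cc")
        assert not res.converged
        assert any("non-physical" in f for f in res.flags)
        assert not (0.0 < res.tau < float("inf"))
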