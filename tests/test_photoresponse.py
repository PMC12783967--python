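"""Hill, Lamb–Pugh and recovery fits: exactness, equivariance, recovery."""

import dataclasses
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rodnoise as rn
from rodnoise.photoresponse import (
    HillModel,
    LambPughModel,
    RecoveryModel,
    average_dim_flash_response,
    fit_hill,
    hill_fraction,
    measure_flash_metrics,
)
from rodnoise.traces import FlashFamily, Trace


def _trace(samples, fs=10_000.0, t0=2000, kind="rod_current"):
    return Trace(np.asarray(samples, float), fs, 300.0, t0, kind)


class TestFlashMetrics:
    def test_round_trip_of_crafted_peak(self):
        # 24 pA peak placed 143 ms after stimulus onset
        fs, t0 = 10_000.0, 2000
        n = t0 + 5000
        y = np.zeros(n)
        peak_idx = t0 + int(0.143 * fs)
        bump = 24.0 * np.hanning(401)  # maximum at the central sample
        y[peak_idx - 200 : peak_idx + 201] = bump
        m = measure_flash_metrics(_trace(y))
        assert m.i_max == pytest.approx(24.0)
        assert m.t_peak_ms == pytest.approx(143.0, abs=0.1)

    def test_flat_trace_flagged(self):
        with pytest.warns(UserWarning, match="flat"):
            m = measure_flash_metrics(_trace(np.zeros(5000)))
        assert m.i_max == 0.0 and math.isnan(m.t_peak_ms) and m.flagged

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        y = np.zeros(8000)
        y[3000:5000] = -np.hanning(2000) * 10
        y += rng.normal(0, 0.1, len(y))
        m1 = measure_flash_metrics(_trace(y))
        m2 = measure_flash_metrics(_trace(y + 17.3))
        assert m1.i_max == pytest.approx(m2.i_max, rel=1e-12)
        assert m1.t_peak_ms == m2.t_peak_ms


class TestHill:
    def test_midpoint_and_simple_values(self):
        assert hill_fraction(20.8, 20.8, 1.3) == pytest.approx(0.5)
        assert hill_fraction(2.0, 1.0, 1.0) == pytest.approx(2.0 / 3.0)
        assert hill_fraction(0.0, 5.0, 2.0) == 0.0

    @given(
        i_half=st.floats(0.5, 100.0),
        n=st.floats(0.5, 4.0),
    )
    def test_monotone_and_bounded(self, i_half, n):
        grid = np.geomspace(1e-3, 1e4, 200)
        vals = hill_fraction(grid, i_half, n)
        assert np.all(vals >= 0.0) and np.all(vals < 1.0)
        assert np.all(np.diff(vals) > 0)

    def test_noise_free_parameter_recovery(self, wt):
        strengths = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0])
        amps = wt.r_max * hill_fraction(strengths, wt.i_half, wt.hill_n)
        fit = fit_hill(np.column_stack([strengths, amps]))
        assert fit.i_half == pytest.approx(20.8, rel=1e-3)
        assert fit.hill_n == pytest.approx(1.3, rel=1e-3)
        assert fit.r_max == pytest.approx(23.4, rel=1e-3)
        assert fit.reliable and not fit.degenerate

    def test_strength_scale_equivariance(self):
        strengths = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 64.0])
        amps = 10.0 * hill_fraction(strengths, 5.0, 1.2)
        base = HillModel(strengths, amps).fit()
        scaled = HillModel(strengths * 7.0, amps).fit()
        assert scaled.i_half == pytest.approx(7.0 * base.i_half, rel=1e-6)
        assert scaled.hill_n == pytest.approx(base.hill_n, rel=1e-6)

    def test_constant_amplitudes_degenerate(self):
        fit = HillModel([1, 2, 4, 8], [5.0, 5.0, 5.0, 5.0]).fit()
        assert fit.degenerate and not fit.reliable
        assert math.isnan(fit.i_half)

    def test_non_spanning_data_flagged_unreliable(self):
        # all points far below half-maximum of the underlying curve
        strengths = np.array([0.01, 0.02, 0.04, 0.08])
        amps = 20.0 * hill_fraction(strengths, 50.0, 1.0)
        fit = HillModel(strengths, amps).fit()
        assert not fit.reliable


class TestLambPughEnsemble:
    def test_noise_free_exact_recovery(self, wt, quiet_config):
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        res = LambPughModel(fam).fit()
        assert res.amplification == pytest.approx(wt.gain_a, rel=0.01)
        assert res.t_delay == pytest.approx(wt.t_delay, abs=2e-4)

    def test_noise_free_single_flash_zero_residual(self, wt):
        # exact model data (pure activation, no cross-fade, no recovery)
        fs, t0 = 10_000.0, 1000
        tt = np.arange(1500) / fs
        phi = 32.0
        y = rn.lamb_pugh_response(tt, phi, 4.2, 0.004, 20.0)
        samples = np.concatenate([np.zeros(t0), -y])
        fam = FlashFamily([phi], [_trace(samples, t0=t0)])
        res = LambPughModel(fam, r_max=20.0).fit()
        assert res.amplification == pytest.approx(4.2, rel=1e-4)
        assert res.t_delay == pytest.approx(0.004, abs=1e-5)
        assert res.residual_norm < 1e-6

    def test_phi_rescaling_confound(self, wt, quiet_config):
        """Multiplying every Φ by k and refitting divides A by k: only
        the A·Φ product is identified."""
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        base = LambPughModel(fam).fit()
        scaled = LambPughModel(fam, phi_list=fam.stimuli * 4.0).fit()
        assert scaled.amplification == pytest.approx(base.amplification / 4.0, rel=1e-3)

    def test_error_when_no_flash_activates(self, wt, quiet_config):
        cfg = dataclasses.replace(
            quiet_config, flash_ladder=(0.05, 0.1, 0.2, 0.4)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = rn.generate_flash_family(wt, cfg, seed=0)
        with pytest.raises(ValueError, match="20%"):
            LambPughModel(fam, r_max=wt.r_max).fit()

    def test_fixed_delay_variant(self, wt, quiet_config):
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        res = LambPughModel(fam, fix_t_delay=wt.t_delay).fit()
        assert res.t_delay == wt.t_delay
        assert res.amplification == pytest.approx(wt.gain_a, rel=0.01)

    def test_noisy_recovery_bias_below_five_percent(self, wt):
        fits = [
            LambPughModel(rn.generate_flash_family(wt, seed=s)).fit().amplification
            for s in range(12)
        ]
        assert np.mean(fits) == pytest.approx(wt.gain_a, rel=0.05)


class TestRecovery:
    def test_pure_exponential_tail(self, wt, quiet_config):
        """Noise-free dim flash generated with tau 251 ms refits within 2%."""
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        avg = average_dim_flash_response(fam, r_max=wt.r_max)
        res = RecoveryModel(avg).fit()
        assert res.tau_ms == pytest.approx(251.0, rel=0.02)

    def test_time_rescaling_doubles_tau(self, wt, quiet_config):
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        avg = average_dim_flash_response(fam, r_max=wt.r_max)
        tau1 = RecoveryModel(avg).fit().tau_ms
        stretched = Trace(
            avg.samples, avg.sampling_rate / 2, 100.0, avg.t0, avg.kind
        )
        tau2 = RecoveryModel(stretched).fit().tau_ms
        assert tau2 == pytest.approx(2 * tau1, rel=1e-9)

    def test_noisy_tau_within_ten_percent(self, wt, quiet_config):
        """Additive noise at 10% of peak: mean tau over 20 seeds within
        10% of the generating value."""
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        avg = average_dim_flash_response(fam, r_max=wt.r_max)
        peak = np.max(np.abs(avg.samples))
        taus = []
        for s in range(20):
            rng = np.random.default_rng([s, 5])
            noisy = Trace(
                avg.samples + rng.normal(0, 0.1 * peak, avg.samples.size),
                avg.sampling_rate, avg.lowpass_cutoff, avg.t0, avg.kind,
            )
            taus.append(RecoveryModel(noisy).fit().tau_ms)
        assert np.mean(taus) == pytest.approx(251.0, rel=0.10)

    def test_error_when_recovery_incomplete(self):
        fs, t0 = 10_000.0, 1000
        y = np.concatenate([np.zeros(t0), -np.linspace(0, 5, 4000)])
        with pytest.raises(ValueError, match="35%"):
            RecoveryModel(_trace(y, t0=t0)).fit()


class TestAverageDimFlash:
    def test_single_dim_flash_returned_unchanged(self, wt, quiet_config):
        fam = rn.generate_flash_family(wt, quiet_config, seed=0)
        # only the dimmest flash qualifies under a tight threshold
        frac0 = rn.hill_fraction(fam.stimuli[0], wt.i_half, wt.hill_n)
        avg = average_dim_flash_response(fam, dim_threshold=1.5 * frac0, r_max=wt.r_max)
        expect = fam.responses[0].samples - fam.responses[0].baseline()
        assert np.allclose(avg.samples, expect[: avg.samples.size])

    def test_linearity_opposite_traces_cancel(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.zeros(2000), rng.normal(0, 1, 3000)])
        fam = FlashFamily([1.0, 2.0], [_trace(x), _trace(-x)])
        avg = average_dim_flash_response(fam, r_max=1e6)
        assert np.allclose(avg.samples, 0.0)

    def test_error_without_dim_flash(self, wt, quiet_config):
        cfg = dataclasses.replace(quiet_config, flash_ladder=(128.0, 256.0, 512.0))
        fam = rn.generate_flash_family(wt, cfg, seed=0)
        with pytest.raises(ValueError, match="dim"):
            average_dim_flash_response(fam, r_max=wt.r_max)
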