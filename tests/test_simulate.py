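"""Generator correctness: model arithmetic, determinism, calibration."""

import dataclasses
import math

import numpy as np
import pytest

import rodnoise as rn
from rodnoise.photoresponse import lamb_pugh_response
from rodnoise.simulate import (
    generate_dark_recording,
    generate_erg_trace,
    generate_flash_family,
    generate_ros_lengths,
    noise_free_flash_response,
)


class TestActivationModel:
    def test_activation_term_arithmetic(self):
        # direct evaluation: 1 - exp(-0.5 * 20 * 3.8 * 0.1^2)
        val = lamb_pugh_response(0.1, phi=20, a=3.8, t_delay=0.0, r_max=1.0)
        assert val == pytest.approx(1.0 - math.exp(-0.38), rel=1e-12)

    def test_no_response_before_delay(self):
        t = np.array([0.0, 0.001, 0.003])
        assert np.all(lamb_pugh_response(t, 50, 4.0, 0.003, 24.0) == 0.0)

    def test_saturates_at_r_max_for_bright_flash(self):
        val = lamb_pugh_response(0.2, phi=1e9, a=3.8, t_delay=0.0, r_max=24.0)
        assert val == pytest.approx(24.0, rel=1e-9)

    def test_quadratic_onset_small_time_limit(self, wt):
        # for 0.5*phi*A*t^2 <= 0.01 the saturating exponential is
        # quadratic to within 1%
        phi, a = 20.0, wt.gain_a
        t = math.sqrt(2 * 0.01 / (phi * a))
        exact = lamb_pugh_response(t, phi, a, 0.0, 1.0)
        quad = 0.5 * phi * a * t**2
        assert exact == pytest.approx(quad, rel=0.01)


class TestFlashFamily:
    def test_seed_determinism(self, wt):
        fam1 = generate_flash_family(wt, seed=42)
        fam2 = generate_flash_family(wt, seed=42)
        for a, b in zip(fam1.responses, fam2.responses):
            assert np.array_equal(a.samples, b.samples)
        fam3 = generate_flash_family(wt, seed=43)
        assert not np.array_equal(
            fam1.responses[0].samples, fam3.responses[0].samples
        )

    def test_distinct_streams_per_cell(self, wt):
        fams = rn.generate_flash_families(wt, n_cells=2, seed=0)
        assert not np.array_equal(
            fams[0].responses[0].samples, fams[1].responses[0].samples
        )

    def test_noise_free_peaks_follow_hill(self, wt, quiet_config):
        """The cross-faded waveform peaks must satisfy the generating
        Hill relation within 5%."""
        fam = generate_flash_family(wt, quiet_config, seed=0)
        for phi, tr in zip(fam.stimuli, fam.responses):
            peak = np.max(np.abs(tr.samples))
            expected = wt.r_max * rn.hill_fraction(phi, wt.i_half, wt.hill_n)
            assert peak == pytest.approx(expected, rel=0.05)

    def test_sharp_crossfade_preserves_hill_round_trip(self, wt, quiet_config):
        """With a zero-width cross-fade the peaks are exactly the Hill
        amplitudes, so refitting recovers the generating parameters."""
        cfg = dataclasses.replace(quiet_config, crossfade_width=0.0)
        fam = generate_flash_family(wt, cfg, seed=0)
        peaks = [np.max(np.abs(tr.samples)) for tr in fam.responses]
        fit = rn.HillModel(fam.stimuli, peaks).fit()
        assert fit.i_half == pytest.approx(wt.i_half, rel=2e-3)
        assert fit.hill_n == pytest.approx(wt.hill_n, rel=2e-3)

    def test_rejects_short_duration(self, wt):
        cfg = dataclasses.replace(rn.SimulationConfig(), duration=0.5)
        with pytest.raises(ValueError, match="tau_rec"):
            generate_flash_family(wt, cfg)

    def test_rejects_non_positive_strength(self):
        with pytest.raises(ValueError, match="positive"):
            rn.SimulationConfig(flash_ladder=(0.0, 2.0))

    def test_warns_on_non_saturating_ladder(self, wt):
        cfg = dataclasses.replace(
            rn.SimulationConfig(), flash_ladder=(2.0, 4.0, 8.0, 16.0)
        )
        with pytest.warns(UserWarning, match="0.95"):
            generate_flash_family(wt, cfg, seed=0)

    def test_response_sign_is_negative_going(self, wt, quiet_config):
        fam = generate_flash_family(wt, quiet_config, seed=0)
        tr = fam.responses[-1]
        assert np.min(tr.samples) < -0.9 * wt.r_max * 0.9


class TestDarkRecording:
    def test_zero_cellular_power_gives_identical_statistics(self, wt):
        preset = dataclasses.replace(wt, cellular_band_power=0.0)
        ratios = []
        for seed in range(8):
            rec = generate_dark_recording(preset, seed=seed)
            sat = rec.saturated_epoch.samples[rec.saturated_epoch.samples.size // 2 :]
            ratios.append(np.var(rec.dark_epoch.samples) / np.var(sat))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_parseval_calibration_of_shaped_noise(self, wt, short_dark_config):
        """Mean directly-integrated 0.6-10 Hz power of the shaped
        cellular noise matches the preset band power within 10%."""
        preset = dataclasses.replace(wt, instrument_sd=1e-12)
        vals = []
        for seed in range(50):
            rec = generate_dark_recording(preset, short_dark_config, seed=seed)
            vals.append(rn.band_power(rn.estimate_psd(rec.dark_epoch)))
        assert np.mean(vals) == pytest.approx(wt.cellular_band_power, rel=0.10)

    def test_instrument_sd_does_not_shift_cellular_recovery(
        self, wt, short_dark_config
    ):
        """Doubling the instrumental noise leaves the spectrally
        subtracted cellular band power unchanged in expectation."""
        loud = dataclasses.replace(wt, instrument_sd=2 * wt.instrument_sd)
        a = [
            rn.analyze_noise(
                generate_dark_recording(wt, short_dark_config, seed=s)
            ).cumulative_power
            for s in range(25)
        ]
        b = [
            rn.analyze_noise(
                generate_dark_recording(loud, short_dark_config, seed=s)
            ).cumulative_power
            for s in range(25)
        ]
        se = math.hypot(np.std(a) / 5, np.std(b) / 5)
        assert abs(np.mean(a) - np.mean(b)) < 3 * se

    def test_rejects_short_dark_epoch(self, wt):
        cfg = dataclasses.replace(rn.SimulationConfig(), dark_duration=10.0)
        with pytest.raises(ValueError, match="20 s"):
            generate_dark_recording(wt, cfg)

    def test_rejects_negative_band_power(self, wt):
        with pytest.raises(ValueError):
            dataclasses.replace(wt, cellular_band_power=-0.1)


class TestRosLengths:
    def test_single_component_mean(self, wt):
        lengths = generate_ros_lengths(wt, 10_000, seed=0)
        assert lengths.mean() == pytest.approx(27.5, abs=0.2)

    def test_degenerate_weight_draws_one_component(self):
        preset = dataclasses.replace(
            rn.get_preset("WT", "PM3"), ros_mixture=((10.0, 1.0, 1.0), (100.0, 1.0, 0.0))
        )
        lengths = generate_ros_lengths(preset, 5000, seed=1)
        assert np.all(lengths < 50.0)

    def test_tail_fraction_matches_numeric_mixture_cdf(self, ko_pm9):
        """Empirical mass above the midpoint between component means
        equals the mixture tail probability from brute-force numerical
        integration of the two Gaussian densities."""
        (m1, w1, p1), (m2, w2, p2) = ko_pm9.ros_mixture
        mid = 0.5 * (m1 + m2)
        x = np.linspace(mid, 120.0, 200_001)

        def gauss(m, fwhm):
            s = fwhm / (2 * math.sqrt(2 * math.log(2)))
            return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))

        tail = np.trapezoid(p1 * gauss(m1, w1) + p2 * gauss(m2, w2), x)
        lengths = generate_ros_lengths(ko_pm9, 100_000, seed=2)
        assert np.mean(lengths > mid) == pytest.approx(tail, abs=0.01)

    def test_seed_reproducibility(self, wt):
        assert np.array_equal(
            generate_ros_lengths(wt, 100, seed=7),
            generate_ros_lengths(wt, 100, seed=7),
        )

    def test_rejects_empty_request(self, wt):
        with pytest.raises(ValueError):
            generate_ros_lengths(wt, 0)


class TestErgTrace:
    def test_half_maximal_amplitude_at_i_half(self, wt):
        tr = generate_erg_trace(wt, wt.erg_a_ihalf)
        waves = rn.measure_erg_waves(tr)
        assert waves.a_amplitude == pytest.approx(wt.erg_a_vmax / 2, rel=1e-9)

    def test_near_vmax_at_ladder_top(self, wt):
        tr = generate_erg_trace(wt, 120.0)
        waves = rn.measure_erg_waves(tr)
        assert waves.a_amplitude == pytest.approx(270.0, rel=0.02)

    def test_zero_noise_round_trip_exact(self, ko):
        for s in (0.01, 0.3, 10.0):
            tr = generate_erg_trace(ko, s)
            waves = rn.measure_erg_waves(tr)
            a = ko.erg_a_vmax * rn.hill_fraction(s, ko.erg_a_ihalf, 1.0)
            b = ko.erg_b_vmax * rn.hill_fraction(s, ko.erg_b_ihalf, 1.0)
            assert waves.a_amplitude == pytest.approx(a, rel=1e-9)
            assert waves.b_amplitude == pytest.approx(b, rel=1e-9)
            assert waves.a_trough_time_ms < waves.b_peak_time_ms

    def test_rejects_out_of_range_strength(self, wt):
        with pytest.raises(ValueError, match="0.001"):
            generate_erg_trace(wt, 500.0)
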