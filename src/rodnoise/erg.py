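"""Scotopic ERG a-/b-wave measurement and intensity–response fits.

The a-wave is measured baseline-to-trough (minimum within 5–80 ms after
the flash) and the b-wave trough-to-peak (maximum within 20–300 ms
minus the a-trough value) — the standard ERG convention.  Per-wave
sensitivity is the half-maximal flash strength (I_0.5, cd·s/m²) from
the best-fit Hill relation of amplitude against flash strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .photoresponse import HillModel, HillResults
from .traces import ErgSeries, Trace

__all__ = [
    "ErgWaves",
    "measure_erg_waves",
    "ErgSensitivityModel",
    "ErgSensitivityResults",
    "fit_erg_sensitivity",
]

A_WINDOW = (0.005, 0.080)  # s post-flash searched for the a-trough
B_WINDOW = (0.020, 0.300)  # s post-flash searched for the b-peak


class ErgWaves(NamedTuple):
    a_amplitude: float  # µV, baseline minus trough
    b_amplitude: float  # µV, peak minus trough
    a_trough_time_ms: float
    b_peak_time_ms: float
    flagged: bool  # True when no negative a-deflection was found


def measure_erg_waves(
    trace: Trace,
    a_window: tuple[float, float] = A_WINDOW,
    b_window: tuple[float, float] = B_WINDOW,
    baseline_s: float = 0.02,
) -> ErgWaves:
    """Measure a- and b-wave amplitudes (µV) from one ERG trace.

    Requires at least 20 ms of pre-flash baseline.  A trace with no
    negative deflection in the a-window yields ``a = 0`` flagged; an
    inverted-polarity trace (a-trough later than b-peak) is rejected.
    """
    base = trace.baseline(baseline_s)
    fs = trace.sampling_rate
    y = trace.samples - base

    def _win(lo, hi):
        i0 = trace.t0 + int(round(lo * fs))
        i1 = trace.t0 + int(round(hi * fs)) + 1
        return i0, y[i0:i1]

    ia0, aw = _win(*a_window)
    ib0, bw = _win(*b_window)
    if aw.size == 0 or bw.size == 0:
        raise ValueError("trace too short for the search windows")

    a_idx = ia0 + int(np.argmin(aw))
    trough = float(y[a_idx])
    b_idx = ib0 + int(np.argmax(bw))
    peak = float(y[b_idx])

    flagged = trough >= 0
    if flagged:
        warnings.warn("no negative a-wave deflection found", stacklevel=2)
        a_amp, trough = 0.0, 0.0
    else:
        a_amp = -trough
    if not flagged and a_idx > b_idx:
        raise ValueError("inverted polarity: a-trough occurs after the b-peak")
    b_amp = peak - trough
    return ErgWaves(
        a_amp,
        b_amp,
        (a_idx - trace.t0) / fs * 1e3,
        (b_idx - trace.t0) / fs * 1e3,
        flagged,
    )


@dataclass
class ErgSensitivityResults:
    """Per-wave Hill fits of an ERG intensity series."""

    a_wave: HillResults  # V_max in µV, I_0.5 in cd s/m^2
    b_wave: HillResults
    measurements: list[ErgWaves]

    def summary(self) -> str:
        return "\n".join(
            [
                "ERG intensity-response fits",
                f"  a-wave: I_0.5 = {self.a_wave.i_half:.3g} cd s/m^2, "
                f"V_max = {self.a_wave.r_max:.4g} uV, n = {self.a_wave.hill_n:.3g}",
                f"  b-wave: I_0.5 = {self.b_wave.i_half:.3g} cd s/m^2, "
                f"V_max = {self.b_wave.r_max:.4g} uV, n = {self.b_wave.hill_n:.3g}",
            ]
        )


class ErgSensitivityModel:
    """Hill intensity–response fits for the a- and b-waves of one series.

    Requires at least 5 flash strengths spanning the dynamic range.
    """

    def __init__(self, series: ErgSeries, **wave_kwargs):
        if len(series) < 5:
            raise ValueError("at least 5 flash strengths required")
        self.series = series
        self.wave_kwargs = wave_kwargs

    def fit(self) -> ErgSensitivityResults:
        waves = [
            measure_erg_waves(tr, **self.wave_kwargs) for tr in self.series.traces
        ]
        s = self.series.flashes
        a_fit = HillModel(s, [w.a_amplitude for w in waves]).fit()
        b_fit = HillModel(s, [w.b_amplitude for w in waves]).fit()
        return ErgSensitivityResults(a_fit, b_fit, waves)


def fit_erg_sensitivity(series: ErgSeries, **kwargs) -> ErgSensitivityResults:
    """Fit a- and b-wave Hill sensitivity for one ERG series."""
    return ErgSensitivityModel(series, **kwargs).fit()
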