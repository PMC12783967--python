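"""Flash-response metrics and model fits for single-cell photocurrents.

Three fitted models, each exposed statsmodels-style as a Model class
whose ``fit()`` returns a Results object (thin functional wrappers are
provided for pipeline use):

* :class:`HillModel` — intensity–response sensitivity,
  ``R/R_max = I^n / (I^n + I_0.5^n)``, giving the half-maximal flash
  strength ``I_0.5`` and Hill coefficient ``n``.
* :class:`LambPughModel` — ensemble (joint) fit of the activation model
  ``R(t) = R_max·(1 − exp(−½·Φ·A·(t − t_delay)²))`` to the leading edge
  of every flash in a family, sharing one amplification constant ``A``
  (s⁻²) and delay ``t_delay`` across flashes.
* :class:`RecoveryModel` — single-exponential fit to the final portion
  of a dim-flash response, from the time recovery falls to 35% of peak,
  giving the recovery time constant ``τ_rec`` (ms).

Rod and bipolar photocurrents are analysed as magnitudes after
baseline subtraction (baseline = mean over the 50 ms before stimulus
onset); stored traces keep their native sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

from .traces import FlashFamily, Trace

__all__ = [
    "hill_fraction",
    "hill_model",
    "lamb_pugh_response",
    "measure_flash_metrics",
    "FlashMetrics",
    "HillModel",
    "HillResults",
    "fit_hill",
    "LambPughModel",
    "LambPughResults",
    "fit_lamb_pugh_ensemble",
    "RecoveryModel",
    "RecoveryResults",
    "fit_recovery_tau",
    "average_dim_flash_response",
]

#: peak ≤ this fraction of R_max qualifies a flash as "dim"
#: (quasi-linear range)
DIM_THRESHOLD = 0.2


def hill_fraction(i, i_half: float, n: float):
    """Hill intensity–response fraction ``I^n / (I^n + I_0.5^n)``.

    Evaluates as ``1 / (1 + (I_0.5 / I)^n)`` for numerical stability;
    returns 0 at I = 0, values in [0, 1), strictly increasing in I.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("flash strength must be non-negative")
    if i_half <= 0 or n <= 0:
        raise ValueError("i_half and n must be positive")
    out = np.zeros_like(i)
    pos = i > 0
    out[pos] = 1.0 / (1.0 + (i_half / i[pos]) ** n)
    return out if out.ndim else float(out)


def hill_model(i, fit: "HillResults"):
    """Hill fraction of ``R_max`` at strength ``i`` under a fitted model."""
    return hill_fraction(i, fit.i_half, fit.hill_n)


def lamb_pugh_response(t, phi: float, a: float, t_delay: float, r_max: float):
    """Lamb–Pugh activation-phase response at post-stimulus times ``t`` (s):
    ``R_max·(1 − exp(−½·Φ·A·(t − t_delay)²))``, zero for t ≤ t_delay."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t_delay, 0.0, None)
    return r_max * -np.expm1(-0.5 * phi * a * dt**2)


class FlashMetrics(NamedTuple):
    """Peak amplitude and its latency for one flash response."""

    i_max: float  # |extremum of baseline-subtracted response|, pA
    t_peak_ms: float  # time from stimulus onset to extremum, ms (nan if flat)
    flagged: bool  # True when no response was detected


def measure_flash_metrics(trace: Trace, flat_tol: float = 0.0) -> FlashMetrics:
    """Maximum response amplitude (I_max) and time to peak (T_peak).

    Baseline (mean of the 50 ms before stimulus onset) is subtracted;
    the extremum of the absolute response after onset defines both
    metrics.  A flat trace yields ``I_max = 0`` with a warning and an
    undefined (NaN) ``T_peak``; ties in peak location break to the
    earliest index.
    """
    base = trace.baseline()
    y = np.abs(trace.samples[trace.t0 :] - base)
    i_max = float(np.max(y))
    if i_max <= flat_tol:
        warnings.warn("flat trace: no response detected", stacklevel=2)
        return FlashMetrics(0.0, float("nan"), True)
    idx = int(np.argmax(y))  # argmax returns the earliest maximal index
    return FlashMetrics(i_max, idx / trace.sampling_rate * 1e3, False)


# ---------------------------------------------------------------------------
# Hill sensitivity


@dataclass
class HillResults:
    """Fitted Hill intensity–response parameters."""

    i_half: float  # half-maximal strength I_0.5
    hill_n: float  # Hill coefficient n
    r_max: float  # maximal amplitude
    residual_norm: float
    reliable: bool = True  # False when I_0.5 falls outside the sampled range
    degenerate: bool = False  # True when amplitudes carry no slope information
    strengths: np.ndarray | None = field(default=None, repr=False)
    amplitudes: np.ndarray | None = field(default=None, repr=False)

    def predict(self, i):
        """Model amplitude at strength ``i``."""
        return self.r_max * hill_fraction(i, self.i_half, self.hill_n)

    def summary(self) -> str:
        flags = []
        if not self.reliable:
            flags.append("I_0.5 outside sampled range")
        if self.degenerate:
            flags.append("degenerate (no slope information)")
        lines = [
            "Hill intensity-response fit",
            f"  I_0.5        {self.i_half:.4g}",
            f"  n            {self.hill_n:.4g}",
            f"  R_max        {self.r_max:.4g}",
            f"  ||residual|| {self.residual_norm:.3g}",
        ]
        if flags:
            lines.append("  flags: " + "; ".join(flags))
        return "\n".join(lines)


class HillModel:
    """Least-squares Hill fit to (flash strength, response amplitude)
    pairs from one cell.

    Needs at least 4 points spanning both sides of half-maximum for a
    reliable estimate; a fit whose I_0.5 lands outside the sampled
    strengths is flagged unreliable, and constant amplitudes yield a
    degenerate (all-NaN) flagged result.
    """

    def __init__(self, strengths, amplitudes):
        self.strengths = np.asarray(strengths, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        if self.strengths.shape != self.amplitudes.shape:
            raise ValueError("strengths and amplitudes must align")
        if len(self.strengths) < 4:
            raise ValueError("at least 4 intensity-response points required")
        if np.any(self.strengths <= 0):
            raise ValueError("flash strengths must be positive")

    @classmethod
    def from_family(cls, family: FlashFamily) -> "HillModel":
        peaks = [measure_flash_metrics(tr).i_max for tr in family.responses]
        return cls(family.stimuli, peaks)

    def fit(self) -> HillResults:
        s, amp = self.strengths, self.amplitudes
        if np.ptp(amp) <= 1e-12 * max(np.max(np.abs(amp)), 1e-300):
            return HillResults(
                float("nan"), float("nan"), float("nan"), 0.0,
                reliable=False, degenerate=True, strengths=s, amplitudes=amp,
            )
        amax = float(np.max(amp))
        # initial I_0.5: first strength whose amplitude crosses half max
        above = amp >= amax / 2
        ih0 = float(s[np.argmax(above)]) if above.any() else float(np.median(s))
        p0 = (ih0, 1.5, amax)
        popt, _ = optimize.curve_fit(
            lambda i, ih, n, rm: rm * hill_fraction(i, ih, n),
            s, amp, p0=p0,
            bounds=([1e-12, 0.05, 1e-12], [np.inf, 20.0, np.inf]),
            maxfev=20000,
        )
        ih, n, rm = map(float, popt)
        resid = amp - rm * hill_fraction(s, ih, n)
        reliable = bool(s.min() <= ih <= s.max())
        return HillResults(
            ih, n, rm, float(np.linalg.norm(resid)),
            reliable=reliable, strengths=s, amplitudes=amp,
        )


def fit_hill(points) -> HillResults:
    """Fit the Hill equation to ``(strength, amplitude)`` pairs."""
    pts = np.asarray(points, dtype=float)
    return HillModel(pts[:, 0], pts[:, 1]).fit()


# ---------------------------------------------------------------------------
# Lamb-Pugh ensemble fit


@dataclass
class LambPughResults:
    """Jointly fitted activation parameters for one flash family."""

    amplification: float  # A, s^-2
    t_delay: float  # s
    r_max: float  # pA
    phi_list: np.ndarray
    fit_windows: list[tuple[int, int]]  # per-flash sample ranges (post-onset)
    residuals: list[np.ndarray]  # per-flash residuals, fraction of R_max
    cost: float

    @property
    def residual_norm(self) -> float:
        return math.sqrt(sum(float(r @ r) for r in self.residuals))

    def summary(self) -> str:
        return "\n".join(
            [
                "Lamb-Pugh ensemble (leading-edge) fit",
                f"  A (s^-2)     {self.amplification:.4g}",
                f"  t_delay (ms) {self.t_delay * 1e3:.3g}",
                f"  R_max (pA)   {self.r_max:.4g}",
                f"  flashes      {len(self.phi_list)}",
                f"  ||residual|| {self.residual_norm:.3g} (fraction of R_max)",
            ]
        )


class LambPughModel:
    """Ensemble Lamb–Pugh fit to the leading edges of a flash family.

    One (A, t_delay) pair is fitted jointly across all flashes.  Each
    flash's fit window runs from stimulus onset until the response first
    reaches ``edge_fraction`` (default 50%) of its own peak, or
    ``max_window_s`` (default 80 ms) post-flash, whichever is earlier,
    confining the fit to the activation-dominated phase.  Responses are
    baseline-subtracted and normalised by ``R_max`` (taken from the Hill
    fit of the family's intensity–response relation unless supplied).

    Parameters
    ----------
    family : FlashFamily
    phi_list : sequence of float, optional
        Photoisomerizations per rod per flash; defaults to the family's
        stimulus strengths (already in R*/rod for single-cell data).
    fix_t_delay : float, optional
        Hold the activation delay fixed (s) instead of fitting it.
    """

    def __init__(
        self,
        family: FlashFamily,
        phi_list: Sequence[float] | None = None,
        edge_fraction: float = 0.5,
        max_window_s: float = 0.08,
        fix_t_delay: float | None = None,
        r_max: float | None = None,
    ):
        self.family = family
        self.phi_list = np.asarray(
            family.stimuli if phi_list is None else phi_list, dtype=float
        )
        if len(self.phi_list) != len(family):
            raise ValueError("phi_list must align with the family's stimuli")
        if not 0 < edge_fraction < 1:
            raise ValueError("edge_fraction must lie in (0, 1)")
        self.edge_fraction = edge_fraction
        self.max_window_s = max_window_s
        self.fix_t_delay = fix_t_delay
        self._r_max = r_max

    def fit(self) -> LambPughResults:
        fam = self.family
        fs = fam.sampling_rate
        # polarity-correct each response (noise stays zero-mean) and take
        # peaks from a lightly smoothed copy so noise maxima do not
        # inflate R_max
        w = max(int(round(0.005 * fs)), 1)
        kernel = np.ones(w) / w
        ys, smooths, peaks = [], [], []
        for tr in fam.responses:
            y = tr.samples[tr.t0 :] - tr.baseline()
            sm = np.convolve(y, kernel, mode="same")
            if sm[int(np.argmax(np.abs(sm)))] < 0:
                y, sm = -y, -sm
            ys.append(y)
            smooths.append(sm)
            peaks.append(float(np.max(sm)))
        peaks = np.asarray(peaks)

        r_max = self._r_max
        if r_max is None:
            hill = HillModel(fam.stimuli, peaks).fit()
            r_max = hill.r_max if (hill.reliable and not hill.degenerate) else None
        if r_max is None or not np.isfinite(r_max):
            r_max = float(peaks.max())
        if peaks.max() < 0.2 * r_max:
            raise ValueError(
                "insufficient activation signal: no flash reaches 20% of R_max"
            )

        max_win = int(round(self.max_window_s * fs))
        windows, ts, fracs = [], [], []
        for y, sm, peak in zip(ys, smooths, peaks):
            crossing = np.nonzero(sm >= self.edge_fraction * peak)[0]
            stop = min(int(crossing[0]) if crossing.size else max_win, max_win)
            stop = max(stop, 2)
            windows.append((0, stop))
            ts.append(np.arange(stop) / fs)
            fracs.append(y[:stop] / r_max)

        def residuals(params):
            if self.fix_t_delay is None:
                a, td = params
            else:
                a, td = params[0], self.fix_t_delay
            return np.concatenate(
                [
                    frac - lamb_pugh_response(t, phi, a, td, 1.0)
                    for frac, t, phi in zip(fracs, ts, self.phi_list)
                ]
            )

        lo, hi = ([1e-9, 0.0], [np.inf, 0.02])
        best = None
        for a0 in (1.0, 5.0, 25.0):
            x0 = [a0, 0.003]
            if self.fix_t_delay is not None:
                x0, lo_, hi_ = x0[:1], lo[:1], hi[:1]
            else:
                lo_, hi_ = lo, hi
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo_, hi_), method="trf"
            )
            if best is None or sol.cost < best.cost:
                best = sol
        a_fit = float(best.x[0])
        td_fit = (
            float(self.fix_t_delay) if self.fix_t_delay is not None
            else float(best.x[1])
        )
        per_flash = [
            frac - lamb_pugh_response(t, phi, a_fit, td_fit, 1.0)
            for frac, t, phi in zip(fracs, ts, self.phi_list)
        ]
        return LambPughResults(
            a_fit, td_fit, float(r_max), self.phi_list, windows,
            per_flash, float(best.cost),
        )


def fit_lamb_pugh_ensemble(
    family: FlashFamily, phi_list=None, **kwargs
) -> LambPughResults:
    """Joint leading-edge Lamb–Pugh fit of a flash family."""
    return LambPughModel(family, phi_list, **kwargs).fit()


# ---------------------------------------------------------------------------
# Dim-flash recovery


@dataclass
class RecoveryResults:
    """Single-exponential recovery-tail fit."""

    tau_ms: float  # recovery time constant
    fit_start_index: int  # absolute sample index where the fit begins
    amplitude_at_start: float  # pA, magnitude at the fit start
    residual_norm: float

    def summary(self) -> str:
        return "\n".join(
            [
                "Recovery tail fit (final 35% of peak)",
                f"  tau_rec (ms)  {self.tau_ms:.4g}",
                f"  start index   {self.fit_start_index}",
                f"  amp at start  {self.amplitude_at_start:.4g} pA",
                f"  ||residual||  {self.residual_norm:.3g}",
            ]
        )


class RecoveryModel:
    """Exponential fit to the final phase of a dim-flash response.

    ``a·exp(−t/τ)`` is least-squares fitted to the baseline-subtracted
    response magnitude from the time recovery first falls to
    ``fraction`` (default 35%) of peak until return to baseline
    (``baseline_fraction`` of peak, or trace end).  The response should
    be sub-saturating (peak below 20% of ``r_max``, when known) so the
    recovery is quasi-linear.
    """

    def __init__(
        self,
        trace: Trace,
        fraction: float = 0.35,
        baseline_fraction: float = 0.02,
        r_max: float | None = None,
    ):
        if not 0 < fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        self.trace = trace
        self.fraction = fraction
        self.baseline_fraction = baseline_fraction
        self.r_max = r_max

    def fit(self) -> RecoveryResults:
        tr = self.trace
        y = tr.samples[tr.t0 :] - tr.baseline()
        # peak and threshold crossings are located on a lightly smoothed
        # envelope so noise maxima neither inflate the peak nor truncate
        # the fitted segment; the raw samples are what gets fitted
        w = max(int(round(0.025 * tr.sampling_rate)), 1)
        smooth = np.convolve(y, np.ones(w) / w, mode="same")
        peak_idx = int(np.argmax(np.abs(smooth)))
        # rectify to a positive-going response; noise stays zero-mean
        if smooth[peak_idx] < 0:
            y, smooth = -y, -smooth
        peak = float(smooth[peak_idx])
        if peak == 0:
            raise ValueError("flat trace: nothing to fit")
        if self.r_max is not None and peak > DIM_THRESHOLD * self.r_max:
            warnings.warn(
                "response exceeds 20% of R_max; recovery fit assumes a "
                "dim (quasi-linear) response",
                stacklevel=2,
            )
        tail = smooth[peak_idx:]
        below = np.nonzero(tail <= self.fraction * peak)[0]
        if below.size == 0:
            raise ValueError(
                "recovery never falls below "
                f"{self.fraction:.0%} of peak within the trace"
            )
        start = peak_idx + int(below[0])
        done = np.nonzero(smooth[start:] <= self.baseline_fraction * peak)[0]
        stop = start + (int(done[0]) + 1 if done.size else len(y) - start)
        seg = y[start:stop]
        if len(seg) < 5:
            raise ValueError("recovery segment too short to fit")
        t = np.arange(len(seg)) / tr.sampling_rate

        a0 = max(float(seg[0]), self.fraction * peak / 2)
        tau0 = max(t[-1] / 3.0, 1.0 / tr.sampling_rate)
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t, seg, p0=(a0, tau0),
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=20000,
        )
        a_fit, tau = map(float, popt)
        resid = seg - a_fit * np.exp(-t / tau)
        return RecoveryResults(
            tau * 1e3, tr.t0 + start, float(seg[0]), float(np.linalg.norm(resid))
        )


def fit_recovery_tau(avg_dim_flash: Trace, **kwargs) -> RecoveryResults:
    """Exponential fit to the final 35% of an average dim-flash response."""
    return RecoveryModel(avg_dim_flash, **kwargs).fit()


def average_dim_flash_response(
    family: FlashFamily,
    dim_threshold: float = DIM_THRESHOLD,
    r_max: float | None = None,
) -> Trace:
    """Pointwise mean of the baseline-subtracted dim-flash responses.

    A flash is dim when its peak is at most ``dim_threshold`` of
    ``r_max`` (default: largest peak in the family).  Raises when no
    flash qualifies.
    """
    peaks, ys = [], []
    for tr in family.responses:
        y = tr.samples - tr.baseline()
        ys.append(y)
        peaks.append(float(np.max(np.abs(y[tr.t0 :]))))
    if r_max is None:
        r_max = max(peaks)
    dims = [y for y, p in zip(ys, peaks) if p <= dim_threshold * r_max]
    if not dims:
        raise ValueError("no flash qualifies as dim under the threshold")
    n = min(map(len, dims))
    mean = np.mean([y[:n] for y in dims], axis=0)
    proto = family.responses[0]
    return Trace(
        mean, proto.sampling_rate, proto.lowpass_cutoff, proto.t0, proto.kind
    )
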