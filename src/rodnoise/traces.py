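"""Core data containers for sampled recordings and flash stimuli.

A :class:`Trace` is a uniformly sampled current (pA) or voltage (µV)
record with acquisition metadata: sampling rate, the analog low-pass
cutoff applied during recording, the sample index of stimulus onset, and
the kind of signal.  Flash families, dark-noise recordings and ERG
series are thin aggregates of traces plus per-cell / per-animal
metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Trace",
    "CellMetadata",
    "FlashFamily",
    "NoiseRecording",
    "ErgSeries",
    "TRACE_UNITS",
]

#: signal kind -> physical unit of the samples
TRACE_UNITS = {
    "rod_current": "pA",
    "rbc_current": "pA",
    "erg_voltage": "uV",
}


@dataclass
class Trace:
    """Uniformly sampled current or voltage trace.

    Parameters
    ----------
    samples : ndarray
        Sample values, pA for currents and µV for ERG voltages.
    sampling_rate : float
        Samples per second (Hz).
    lowpass_cutoff : float
        Analog low-pass filter cutoff applied at acquisition (Hz); must
        lie below the Nyquist frequency.
    t0 : int
        Index of stimulus onset (0 for stimulus-free recordings).
    kind : str
        One of ``rod_current``, ``rbc_current``, ``erg_voltage``.
    """

    samples: np.ndarray
    sampling_rate: float
    lowpass_cutoff: float
    t0: int = 0
    kind: str = "rod_current"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.lowpass_cutoff < self.sampling_rate / 2:
            raise ValueError(
                "lowpass_cutoff must be below the Nyquist frequency "
                f"({self.sampling_rate / 2} Hz)"
            )
        if not 0 <= self.t0 < len(self.samples):
            raise ValueError("t0 must index into samples")
        if self.kind not in TRACE_UNITS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def unit(self) -> str:
        return TRACE_UNITS[self.kind]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(len(self.samples)) - self.t0) / self.sampling_rate

    def baseline(self, window_s: float = 0.05) -> float:
        """Mean of the pre-stimulus samples over the final ``window_s``
        seconds before onset."""
        n = int(round(window_s * self.sampling_rate))
        if self.t0 < n:
            raise ValueError(
                f"need {window_s * 1e3:.0f} ms of pre-stimulus baseline, "
                f"trace has {self.t0 / self.sampling_rate * 1e3:.1f} ms"
            )
        return float(np.mean(self.samples[self.t0 - n : self.t0]))

    def copy(self) -> "Trace":
        return dataclasses.replace(self, samples=self.samples.copy())


@dataclass
class CellMetadata:
    """Bookkeeping for a recorded cell or animal."""

    genotype: str = "WT"
    age: str = "PM3"
    holding_potential: float = -40.0  # mV
    junction_correction: float = -10.0  # mV, applied at most once
    v_m: float | None = None  # resting membrane potential, mV
    capacitance: float | None = None  # pF
    cell_id: str = ""


@dataclass
class FlashFamily:
    """Ordered (flash strength, averaged response) pairs for one cell.

    ``stimuli`` are flash strengths in R*/rod (single-cell recordings)
    or cd·s/m² (ERG), strictly increasing; each strength has one
    averaged response trace; all responses share a sampling rate.
    """

    stimuli: np.ndarray
    responses: list[Trace]
    metadata: CellMetadata = field(default_factory=CellMetadata)

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        if len(self.stimuli) != len(self.responses):
            raise ValueError("one response trace per stimulus required")
        if np.any(self.stimuli <= 0):
            raise ValueError("flash strengths must be positive")
        if np.any(np.diff(self.stimuli) <= 0):
            raise ValueError("flash strengths must be strictly increasing")
        rates = {tr.sampling_rate for tr in self.responses}
        if len(rates) > 1:
            raise ValueError("all responses must share a sampling rate")

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def sampling_rate(self) -> float:
        return self.responses[0].sampling_rate


@dataclass
class NoiseRecording:
    """Dark-noise recording pair from one rod.

    ``dark_epoch`` is membrane current in complete darkness;
    ``saturated_epoch`` is current during/after a saturating flash
    (~200 R*/rod) that closes all CNG channels, leaving only
    instrumental noise.  Both epochs share a sampling rate.
    """

    dark_epoch: Trace
    saturated_epoch: Trace
    metadata: CellMetadata = field(default_factory=CellMetadata)
    #: seconds discarded from the start of the saturated epoch when it is
    #: used as an instrumental-noise estimate (flash-response transient)
    saturated_transient: float = 0.5

    def __post_init__(self) -> None:
        if self.dark_epoch.sampling_rate != self.saturated_epoch.sampling_rate:
            raise ValueError("epochs must share a sampling rate")


@dataclass
class ErgSeries:
    """Scotopic ERG intensity series for one animal: flash strengths in
    cd·s/m² with one averaged voltage trace each."""

    flashes: np.ndarray
    traces: list[Trace]
    metadata: CellMetadata = field(default_factory=CellMetadata)

    def __post_init__(self) -> None:
        self.flashes = np.asarray(self.flashes, dtype=float)
        if len(self.flashes) != len(self.traces):
            raise ValueError("one trace per flash strength required")
        if np.any(np.diff(self.flashes) <= 0):
            raise ValueError("flash strengths must be strictly increasing")
        rates = {tr.sampling_rate for tr in self.traces}
        if len(rates) > 1:
            raise ValueError("all traces must share a sampling rate")

    def __len__(self) -> int:
        return len(self.flashes)
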