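"""Genotype/age presets and simulation configuration.

The presets collect the published response properties of WT and
GARP2-KO mouse rods at three ages (postnatal months 3, 6 and 9): Hill
sensitivity parameters and saturating current of single-rod flash
families, Lamb–Pugh amplification constant, dim-flash recovery time
constant, band-limited (0.6–10 Hz) continuous dark-noise power, ERG
a-/b-wave Naka–Rushton parameters, and the rod-outer-segment (ROS)
length distribution.  They are the generating ("ground truth") values
of the synthetic-data module, so each downstream analysis can be tested
as a parameter-recovery problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypePreset",
    "SimulationConfig",
    "get_preset",
    "PRESETS",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class GenotypePreset:
    """Generating parameters for one genotype × age condition.

    Units: ``gain_a`` s⁻²; ``t_delay`` s; ``r_max`` pA; ``i_half``
    R*/rod; ``tau_rec`` ms; ``cellular_band_power`` pA² over 0.6–10 Hz;
    ``instrument_sd`` pA; ROS mixture components are
    (mean µm, FWHM µm, weight) with weights summing to 1; ERG
    amplitudes in µV and half-saturating strengths in cd·s/m².
    """

    label: str  # "WT" | "GARP2KO"
    age: str  # "PM3" | "PM6" | "PM9"
    gain_a: float  # amplification constant A, s^-2
    t_delay: float  # activation delay, s
    r_max: float  # saturating response amplitude, pA
    i_half: float  # half-maximal flash strength, R*/rod
    hill_n: float  # Hill coefficient
    tau_rec: float  # recovery time constant, ms
    t_peak: float  # nominal time to peak, ms (bookkeeping)
    v_m: float  # resting membrane potential, mV
    capacitance: float  # pF
    cellular_band_power: float  # pA^2 in 0.6-10 Hz
    instrument_sd: float  # pA, white instrumental noise
    ros_mixture: tuple[tuple[float, float, float], ...]
    erg_a_vmax: float  # uV
    erg_a_ihalf: float  # cd s / m^2
    erg_b_vmax: float  # uV
    erg_b_ihalf: float  # cd s / m^2
    erg_hill_n: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "gain_a",
            "r_max",
            "i_half",
            "hill_n",
            "tau_rec",
            "erg_a_vmax",
            "erg_a_ihalf",
            "erg_b_vmax",
            "erg_b_ihalf",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hill_n < 0.5:
            raise ValueError("hill_n must be >= 0.5")
        if self.cellular_band_power < 0:
            raise ValueError("cellular_band_power must be non-negative")
        weights = [w for _, _, w in self.ros_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("ros_mixture weights must sum to 1")
        if any(fwhm <= 0 for _, fwhm, _ in self.ros_mixture):
            raise ValueError("ros_mixture FWHMs must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition/stimulus settings for the synthetic generator.

    ``flash_ladder`` strengths (R*/rod) double flash-to-flash by
    default, spanning just-measurable to saturating; single-cell traces
    are sampled at 10 kHz after a 300 Hz low-pass, matching the
    recording conditions the analyses assume.
    """

    sampling_rate: float = 10_000.0  # Hz
    lowpass_cutoff: float = 300.0  # Hz
    duration: float = 2.0  # s of post-stimulus recording
    pre_stimulus: float = 0.2  # s of baseline before the flash
    flash_ladder: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0)
    flash_noise_sd: float = 0.3  # pA, additive, after 300 Hz low-pass
    crossfade_width: float = 0.010  # s, raised-cosine activation->recovery blend
    dark_duration: float = 60.0  # s of dark epoch
    saturated_duration: float = 15.0  # s of saturated (instrumental) epoch
    noise_corner_hz: float = 3.0  # 2-pole low-pass corner of cellular noise
    seed: int = 0
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.sampling_rate < 2 * 10.0:
            raise ValueError("sampling_rate must be at least twice the 10 Hz band edge")
        ladder = np.asarray(self.flash_ladder, dtype=float)
        if np.any(ladder <= 0):
            raise ValueError("flash strengths must be positive")
        if np.any(np.diff(ladder) <= 0):
            raise ValueError("flash_ladder must be strictly increasing")


def _mk(label, age, **kw):
    return GenotypePreset(label=label, age=age, **kw)


_WT_ROS = ((27.5, 7.0, 1.0),)
_KO_ROS = ((26.8, 7.2, 0.77), (34.0, 7.0, 0.23))

# Generating values per genotype x age.  Single-rod rows (i_half, r_max,
# hill_n, t_peak, v_m, capacitance, band power) are age-specific; the
# amplification constant and recovery time constant were characterized at
# PM6 and are reused across ages.
_COMMON_WT = dict(gain_a=3.8, tau_rec=251.0, ros_mixture=_WT_ROS)
_COMMON_KO = dict(gain_a=3.9, tau_rec=233.0, ros_mixture=_KO_ROS)
_ACQ = dict(t_delay=0.003, instrument_sd=1.0)

PRESETS: dict[tuple[str, str], GenotypePreset] = {}
for p in [
    _mk("WT", "PM3", i_half=20.8, r_max=23.4, hill_n=1.3, t_peak=143, v_m=-34.6,
        capacitance=3.6, cellular_band_power=0.17, erg_a_vmax=270, erg_a_ihalf=1.7,
        erg_b_vmax=516, erg_b_ihalf=0.03, **_COMMON_WT, **_ACQ),
    _mk("WT", "PM6", i_half=21.4, r_max=24.8, hill_n=1.4, t_peak=144, v_m=-36.2,
        capacitance=3.5, cellular_band_power=0.20, erg_a_vmax=282, erg_a_ihalf=1.1,
        erg_b_vmax=505, erg_b_ihalf=0.01, **_COMMON_WT, **_ACQ),
    _mk("WT", "PM9", i_half=24.0, r_max=27.0, hill_n=1.3, t_peak=135, v_m=-35.0,
        capacitance=4.3, cellular_band_power=0.18, erg_a_vmax=236, erg_a_ihalf=1.5,
        erg_b_vmax=396, erg_b_ihalf=0.03, **_COMMON_WT, **_ACQ),
    _mk("GARP2KO", "PM3", i_half=16.5, r_max=26.8, hill_n=1.3, t_peak=132, v_m=-32.2,
        capacitance=3.4, cellular_band_power=0.07, erg_a_vmax=246, erg_a_ihalf=2.0,
        erg_b_vmax=447, erg_b_ihalf=0.03, **_COMMON_KO, **_ACQ),
    _mk("GARP2KO", "PM6", i_half=21.7, r_max=22.3, hill_n=1.4, t_peak=136, v_m=-35.9,
        capacitance=3.8, cellular_band_power=0.09, erg_a_vmax=284, erg_a_ihalf=1.0,
        erg_b_vmax=488, erg_b_ihalf=0.01, **_COMMON_KO, **_ACQ),
    _mk("GARP2KO", "PM9", i_half=27.3, r_max=24.7, hill_n=1.1, t_peak=129, v_m=-37.6,
        capacitance=4.5, cellular_band_power=0.17, erg_a_vmax=170, erg_a_ihalf=1.5,
        erg_b_vmax=313, erg_b_ihalf=0.03, **_COMMON_KO, **_ACQ),
]:
    PRESETS[(p.label, p.age)] = p


def get_preset(label: str, age: str = "PM3") -> GenotypePreset:
    """Look up the preset for a genotype (``WT``/``GARP2KO``, ``KO``
    accepted as an alias) and age (``PM3``/``PM6``/``PM9``)."""
    label = {"KO": "GARP2KO"}.get(label.upper(), label.upper())
    key = (label, age.upper())
    if key not in PRESETS:
        raise KeyError(
            f"no preset for {key}; choose from {sorted(PRESETS)}"
        )
    return PRESETS[key]
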