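"""Text-based trace and table I/O, run configuration, and the
end-to-end pipeline.

Traces are stored as two-column CSV (time s, value pA or µV) next to a
JSON sidecar (``<name>.meta.json``) holding units and acquisition
metadata, so a round trip is lossless and unit-checked.  Aggregates
(flash families, noise recordings, ERG series) are directories of
traces plus a manifest JSON.  Analysis outputs are TSV tables matching
the layout of the study's summary tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erg as erg_mod
from . import morphometry, noise, photoresponse, simulate
from .presets import SimulationConfig, get_preset
from .traces import TRACE_UNITS, CellMetadata, ErgSeries, FlashFamily, NoiseRecording, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "write_flash_family",
    "read_flash_family",
    "write_noise_recording",
    "read_noise_recording",
    "write_erg_series",
    "read_erg_series",
    "RunConfig",
    "run_pipeline",
    "analyze_flash_dir",
    "analyze_noise_dir",
    "analyze_erg_dir",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as two-column CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    times = trace.times
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(times, trace.samples):
            fh.write(f"{t:.9g},{v:.17g}\n")
    meta = {
        "unit": trace.unit,
        "kind": trace.kind,
        "sampling_rate": trace.sampling_rate,
        "lowpass_cutoff": trace.lowpass_cutoff,
        "t0": trace.t0,
        "n_samples": len(trace.samples),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(
    path,
    assume_kind: str | None = None,
    assume_rate: float | None = None,
    assume_cutoff: float | None = None,
) -> Trace:
    """Read a trace written by :func:`write_trace`.

    A missing sidecar is an error unless all ``assume_*`` values are
    given explicitly (legacy two-column files); a sidecar with an
    unknown unit or a unit inconsistent with its kind is rejected.
    """
    path = Path(path)
    side = _sidecar(path)
    values = pd.read_csv(path, float_precision="round_trip")["value"].to_numpy(
        dtype=float
    )
    if side.exists():
        meta = json.loads(side.read_text())
        kind = meta["kind"]
        if kind not in TRACE_UNITS:
            raise ValueError(f"unknown trace kind {kind!r} in {side}")
        if meta.get("unit") != TRACE_UNITS[kind]:
            raise ValueError(
                f"unit {meta.get('unit')!r} inconsistent with kind {kind!r}"
            )
        return Trace(
            values, meta["sampling_rate"], meta["lowpass_cutoff"],
            int(meta["t0"]), kind,
        )
    if assume_kind is None or assume_rate is None or assume_cutoff is None:
        raise FileNotFoundError(
            f"no metadata sidecar {side}; pass assume_kind/assume_rate/"
            "assume_cutoff to read a legacy file"
        )
    return Trace(values, assume_rate, assume_cutoff, 0, assume_kind)


def _meta_dict(meta: CellMetadata) -> dict:
    return dataclasses.asdict(meta)


def write_flash_family(family: FlashFamily, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(family.responses):
        name = f"flash_{i:03d}.csv"
        write_trace(tr, directory / name)
        names.append(name)
    manifest = {
        "type": "flash_family",
        "stimuli": list(map(float, family.stimuli)),
        "traces": names,
        "metadata": _meta_dict(family.metadata),
    }
    (directory / "family.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_flash_family(directory) -> FlashFamily:
    directory = Path(directory)
    manifest = json.loads((directory / "family.json").read_text())
    traces = [read_trace(directory / n) for n in manifest["traces"]]
    return FlashFamily(
        np.asarray(manifest["stimuli"]), traces,
        CellMetadata(**manifest["metadata"]),
    )


def write_noise_recording(rec: NoiseRecording, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trace(rec.dark_epoch, directory / "dark.csv")
    write_trace(rec.saturated_epoch, directory / "saturated.csv")
    manifest = {
        "type": "noise_recording",
        "saturated_transient": rec.saturated_transient,
        "metadata": _meta_dict(rec.metadata),
    }
    (directory / "recording.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_noise_recording(directory) -> NoiseRecording:
    directory = Path(directory)
    manifest = json.loads((directory / "recording.json").read_text())
    return NoiseRecording(
        read_trace(directory / "dark.csv"),
        read_trace(directory / "saturated.csv"),
        CellMetadata(**manifest["metadata"]),
        saturated_transient=manifest["saturated_transient"],
    )


def write_erg_series(series: ErgSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, tr in enumerate(series.traces):
        name = f"erg_{i:03d}.csv"
        write_trace(tr, directory / name)
        names.append(name)
    manifest = {
        "type": "erg_series",
        "flashes": list(map(float, series.flashes)),
        "traces": names,
        "metadata": _meta_dict(series.metadata),
    }
    (directory / "series.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_erg_series(directory) -> ErgSeries:
    directory = Path(directory)
    manifest = json.loads((directory / "series.json").read_text())
    traces = [read_trace(directory / n) for n in manifest["traces"]]
    return ErgSeries(
        np.asarray(manifest["flashes"]), traces,
        CellMetadata(**manifest["metadata"]),
    )


# ---------------------------------------------------------------------------
# directory-level analyses (one subdirectory per cell/animal)


def _cell_dirs(directory, manifest_name):
    directory = Path(directory)
    if (directory / manifest_name).exists():
        return [directory]
    subs = sorted(
        d for d in directory.iterdir() if (d / manifest_name).exists()
    )
    if not subs:
        raise FileNotFoundError(f"no {manifest_name} manifests under {directory}")
    return subs


def analyze_flash_dir(
    directory, dim_threshold: float = 0.2, edge_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-cell flash-family analysis table (one row of response
    properties per rod or bipolar cell)."""
    rows = []
    for d in _cell_dirs(directory, "family.json"):
        fam = read_flash_family(d)
        peaks = [photoresponse.measure_flash_metrics(tr) for tr in fam.responses]
        hill = photoresponse.HillModel.from_family(fam).fit()
        lp = photoresponse.LambPughModel(fam, edge_fraction=edge_fraction).fit()
        row = {
            "cell_id": fam.metadata.cell_id or d.name,
            "genotype": fam.metadata.genotype,
            "age": fam.metadata.age,
            "I_max_pA": max(p.i_max for p in peaks),
            "I_half": hill.i_half,
            "hill_n": hill.hill_n,
            "T_peak_ms": peaks[0].t_peak_ms,  # dimmest flash, quasi-linear range
            "A_s2": lp.amplification,
            "t_delay_ms": lp.t_delay * 1e3,
            "V_m_mV": fam.metadata.v_m,
            "C_pF": fam.metadata.capacitance,
        }
        try:
            avg = photoresponse.average_dim_flash_response(
                fam, dim_threshold=dim_threshold
            )
            row["tau_rec_ms"] = photoresponse.RecoveryModel(avg).fit().tau_ms
        except ValueError:
            row["tau_rec_ms"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_noise_dir(
    directory, band=(0.6, 10.0), segment_length: float = 5.0, overlap: float = 0.5
) -> pd.DataFrame:
    """Per-cell dark-noise band power table."""
    rows = []
    for d in _cell_dirs(directory, "recording.json"):
        rec = read_noise_recording(d)
        res = noise.DarkNoiseModel(
            rec, band=band, segment_length=segment_length, overlap=overlap
        ).fit()
        rows.append(
            {
                "cell_id": rec.metadata.cell_id or d.name,
                "genotype": rec.metadata.genotype,
                "age": rec.metadata.age,
                "band_power_pA2": res.cumulative_power,
                "n_segments": res.total_psd.n_segments_averaged,
            }
        )
    return pd.DataFrame(rows)


def analyze_erg_dir(directory) -> pd.DataFrame:
    """Per-animal ERG sensitivity table (I_0.5 and V_max per wave)."""
    rows = []
    for d in _cell_dirs(directory, "series.json"):
        series = read_erg_series(d)
        res = erg_mod.ErgSensitivityModel(series).fit()
        rows.append(
            {
                "animal_id": d.name,
                "genotype": series.metadata.genotype,
                "age": series.metadata.age,
                "I_half_a": res.a_wave.i_half,
                "V_max_a_uV": res.a_wave.r_max,
                "I_half_b": res.b_wave.i_half,
                "V_max_b_uV": res.b_wave.r_max,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class RunConfig:
    """Settings for an end-to-end simulate → analyze → report run."""

    out_dir: str = "rodnoise_run"
    seed: int = 0
    genotypes: tuple[str, ...] = ("WT", "GARP2KO")
    ages: tuple[str, ...] = ("PM3",)
    n_cells: int = 2
    n_ros: int = 400
    band: tuple[float, float] = (0.6, 10.0)
    segment_length: float = 5.0
    overlap: float = 0.5
    dim_threshold: float = 0.2
    edge_fraction: float = 0.5
    dark_duration: float = 20.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validated(self) -> "RunConfig":
        if not 0 < self.dim_threshold < 1:
            raise ValueError("dim_threshold must lie in (0, 1)")
        if not 0 < self.edge_fraction < 1:
            raise ValueError("edge_fraction must lie in (0, 1)")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if 1.0 / self.segment_length > 0.3:
            raise ValueError("segment_length too short to resolve 0.6 Hz")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate, analyse and summarise every configured genotype × age
    condition; returns the output directory.

    Writes simulated traces under ``sim/``, per-cell analysis TSVs under
    ``results/`` and grouped mean ± SD (n) tables under ``tables/``;
    the full configuration is serialised alongside for provenance.
    """
    from .groupstats import render_summary_table

    config = config.validated()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    sim_cfg = dataclasses.replace(
        config.simulation, seed=config.seed, dark_duration=config.dark_duration
    )

    ros_rows = []
    for label in config.genotypes:
        for age in config.ages:
            preset = get_preset(label, age)
            tag = f"{preset.label}_{age}"
            for i in range(config.n_cells):
                fam = simulate.generate_flash_family(preset, sim_cfg, cell_index=i)
                write_flash_family(fam, out / "sim" / "flash" / f"{tag}_cell{i}")
                rec = simulate.generate_dark_recording(preset, sim_cfg, cell_index=i)
                write_noise_recording(rec, out / "sim" / "dark" / f"{tag}_cell{i}")
            series = simulate.generate_erg_series(preset, seed=config.seed)
            write_erg_series(series, out / "sim" / "erg" / tag)
            lengths = simulate.generate_ros_lengths(
                preset, config.n_ros, seed=config.seed
            )
            pd.DataFrame({"length_um": lengths}).to_csv(
                out / "sim" / f"ros_{tag}.tsv", sep="\t", index=False
            )
            k = len(preset.ros_mixture)
            morpho = morphometry.RosMixtureModel(lengths, k=k).fit()
            for j, comp in enumerate(morpho.components, 1):
                ros_rows.append(
                    {
                        "genotype": preset.label, "age": age, "component": j,
                        "center_um": comp.center, "fwhm_um": comp.fwhm,
                        "height": comp.height, "area": comp.area,
                        "fraction_long": (
                            morpho.fraction_long if k == 2 else np.nan
                        ),
                    }
                )

    flash_df = analyze_flash_dir(
        out / "sim" / "flash",
        dim_threshold=config.dim_threshold,
        edge_fraction=config.edge_fraction,
    )
    noise_df = analyze_noise_dir(
        out / "sim" / "dark", band=config.band,
        segment_length=config.segment_length, overlap=config.overlap,
    )
    erg_df = analyze_erg_dir(out / "sim" / "erg")
    ros_df = pd.DataFrame(ros_rows)

    results = out / "results"
    results.mkdir(exist_ok=True)
    flash_df.to_csv(results / "flash.tsv", sep="\t", index=False)
    noise_df.to_csv(results / "noise.tsv", sep="\t", index=False)
    erg_df.to_csv(results / "erg.tsv", sep="\t", index=False)
    ros_df.to_csv(results / "ros.tsv", sep="\t", index=False)

    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    flash_table = render_summary_table(
        flash_df, ["I_max_pA", "I_half", "hill_n", "T_peak_ms", "A_s2", "tau_rec_ms"]
    )
    noise_table = render_summary_table(noise_df, ["band_power_pA2"])
    (tables / "rods.md").write_text(flash_table.to_markdown())
    (tables / "noise.md").write_text(noise_table.to_markdown())
    return out
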