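"""File formats and run configuration.

Interchange is deliberately plain text: traces and protocols travel as CSV
with a ``# key=value`` header block, runs are configured in TOML.  Vendor
acquisition formats (ABF, Nanion/Sophion exports) are out of scope; an
adapter only needs to produce the CSV dialect below to enter the pipeline.

Trace CSV dialect::

    # temperature_C=27.0
    # dilation_factor=2.0
    # cell_id=cell003
    time_ms,current_pA
    0.0,-1.2
    ...

A ``current_pA_per_pF`` column instead of ``current_pA`` marks a
density-normalized trace.  Protocol CSVs use ``voltage_mV`` with
``holding_potential`` in the header.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import GatingModel, apply_variant, default_wt_model, model_from_dict, scale_for_temperature, variant_presets
from .protocol import APShapeParams, VoltageProtocol, build_ap_waveform, dilate
from .simulate import ArtifactParams, CurrentTrace, simulate_population

__all__ = [
    "RunConfig",
    "PopulationConfig",
    "AnalysisConfig",
    "StatsConfig",
    "load_config",
    "save_config",
    "read_trace_csv",
    "write_trace_csv",
    "read_protocol_csv",
    "write_protocol_csv",
    "make_fixtures",
]


class ConfigError(ValueError):
    """Configuration file parse/validation failure, with a field path."""


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class PopulationConfig:
    n_cells: int = 8
    conductance_cv: float = 0.2
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigError("population.n_cells must be >= 1")
        if self.conductance_cv < 0:
            raise ConfigError("population.conductance_cv must be >= 0")


@dataclass(frozen=True)
class AnalysisConfig:
    window_start: float | None = None  # ms; None = trace start
    window_end: float | None = None  # ms; None = trace end
    blank_late_artifact: bool = False


@dataclass(frozen=True)
class StatsConfig:
    test: str = "mannwhitney"  # wilcoxon | mannwhitney | ttest | paired-ttest
    alpha: float = 0.05
    alpha_strong: float = 0.01

    def __post_init__(self):
        if not (0 < self.alpha_strong < self.alpha < 1):
            raise ConfigError("stats: need 0 < alpha_strong < alpha < 1")


@dataclass(frozen=True)
class RunConfig:
    protocol: APShapeParams = field(default_factory=APShapeParams)
    model_file: str | None = None  # None = packaged WT constants
    variant: str = "WT"
    temperatures: tuple = (22.0, 27.0, 32.0, 37.0)
    factors: tuple = (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self):
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        object.__setattr__(self, "factors", tuple(float(f) for f in self.factors))
        if any(not f > 0 for f in self.factors):
            raise ConfigError("factors must all be > 0 (field: factors)")

    def load_model(self) -> GatingModel:
        if self.model_file is None:
            model = default_wt_model()
        else:
            with open(self.model_file, "rb") as fh:
                model = model_from_dict(tomllib.load(fh))
        presets = variant_presets()
        if self.variant not in presets:
            raise ConfigError(
                f"variant {self.variant!r} not among packaged presets {sorted(presets)} (field: variant)"
            )
        return apply_variant(model, presets[self.variant])


_SECTION_TYPES = {
    "protocol": APShapeParams,
    "population": PopulationConfig,
    "analysis": AnalysisConfig,
    "stats": StatsConfig,
    "artifacts": ArtifactParams,
}


def _build_dataclass(cls, doc: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{path}]")
    kwargs = {}
    for key, value in doc.items():
        if isinstance(value, dict):
            sub = _SECTION_TYPES.get(key)
            if sub is None:
                raise ConfigError(f"unexpected table [{path}.{key}]")
            value = _build_dataclass(sub, value, f"{path}.{key}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{path}] section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and fully validate a TOML run configuration.

    Missing keys take their documented defaults; unknown keys are rejected
    with the offending field path.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _build_dataclass(RunConfig, doc, "run")


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig back to TOML (round-trips through load_config)."""

    lines: list[str] = []

    def emit(obj, prefix: str):
        tables = []
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                tables.append((f.name, v))
            elif v is None:
                continue
            elif isinstance(v, (tuple, list)):
                lines.append(f"{f.name} = [{', '.join(_toml_scalar(x) for x in v)}]")
            else:
                lines.append(f"{f.name} = {_toml_scalar(v)}")
        for name, v in tables:
            full = f"{prefix}.{name}" if prefix else name
            lines.append(f"\n[{full}]")
            emit(v, full)

    emit(config, "")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trace / protocol CSV


def _write_kv_csv(path, header: dict, colnames: tuple, columns) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write(",".join(colnames) + "\n")
        for row in zip(*columns):
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")


def _read_kv_csv(path) -> tuple[dict, pd.DataFrame]:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            header[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return header, df


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


_TRACE_KEYS = ("temperature_C", "dilation_factor", "cell_id", "density_normalized")


def write_trace_csv(trace: CurrentTrace, path) -> None:
    """Write a trace in the documented dialect; meta keys go to the header."""
    header = {
        "temperature_C": trace.temperature,
        "dilation_factor": trace.dilation_factor,
        "cell_id": trace.cell_id,
    }
    header.update({k: v for k, v in trace.meta.items() if k not in _TRACE_KEYS})
    col = "current_pA_per_pF" if trace.density_normalized else "current_pA"
    _write_kv_csv(path, header, ("time_ms", col), (trace.times, trace.current))


def read_trace_csv(path) -> CurrentTrace:
    """Read a trace CSV; lossless round-trip of samples and metadata."""
    header, df = _read_kv_csv(path)
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column time_ms")
    density = "current_pA_per_pF" in df.columns
    col = "current_pA_per_pF" if density else "current_pA"
    if col not in df.columns:
        raise ValueError(f"{path}: missing current column (current_pA or current_pA_per_pF)")
    times = df["time_ms"].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time_ms must be strictly increasing")
    meta = {k: _parse_meta(v) for k, v in header.items() if k not in _TRACE_KEYS}
    return CurrentTrace(
        times=times,
        current=df[col].to_numpy(dtype=float),
        temperature=float(header.get("temperature_C", np.nan)),
        dilation_factor=float(header.get("dilation_factor", 1.0)),
        cell_id=header.get("cell_id", ""),
        density_normalized=density,
        meta=meta,
    )


def write_protocol_csv(protocol: VoltageProtocol, path) -> None:
    header = {
        "holding_potential": protocol.holding_potential,
        "dilation_factor": protocol.dilation_factor,
        "label": protocol.label,
    }
    _write_kv_csv(path, header, ("time_ms", "voltage_mV"), (protocol.times, protocol.voltages))


def read_protocol_csv(path) -> VoltageProtocol:
    header, df = _read_kv_csv(path)
    for col in ("time_ms", "voltage_mV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    return VoltageProtocol(
        times=df["time_ms"].to_numpy(dtype=float),
        voltages=df["voltage_mV"].to_numpy(dtype=float),
        holding_potential=float(header["holding_potential"]),
        dilation_factor=float(header.get("dilation_factor", 1.0)),
        label=header.get("label", ""),
    )


# ---------------------------------------------------------------------------
# fixture generator


def make_fixtures(
    out_dir,
    seed: int = 0,
    variants: tuple = ("WT", "R328C", "D591H"),
    temperatures: tuple = (22.0, 27.0, 32.0, 37.0),
    factors: tuple = (0.5, 1.0, 1.5, 2.0, 3.0, 5.0),
    n_cells: int = 8,
    conductance_cv: float = 0.2,
    artifacts: ArtifactParams | None = None,
    protocol_params: APShapeParams | None = None,
) -> pd.DataFrame:
    """Generate a deterministic tree of synthetic trace CSVs plus a manifest.

    One file per cell under ``<variant>/T<temp>_x<factor>/``; the manifest CSV
    indexes every trace.  Regeneration with the same seed is bitwise
    identical.  Defaults mirror the experimental grid (three variants, four
    temperatures, factors 0.5–5) at a reduced cell count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = build_ap_waveform(protocol_params or APShapeParams())
    presets = variant_presets()
    wt = default_wt_model()

    rows = []
    for iv, variant in enumerate(variants):
        model_v = apply_variant(wt, presets[variant])
        for it, temp in enumerate(temperatures):
            model_t = scale_for_temperature(model_v, float(temp))
            for jf, factor in enumerate(factors):
                proto = dilate(base, float(factor))
                combo_seed = int(
                    np.random.SeedSequence([seed, iv, it, jf]).generate_state(1)[0]
                    % (2**31 - 1)
                )
                art = None
                if artifacts is not None:
                    art = dataclasses.replace(artifacts, rng_seed=combo_seed)
                traces = simulate_population(
                    model_t,
                    proto,
                    n_cells=n_cells,
                    conductance_cv=conductance_cv,
                    artifacts=art,
                    rng_seed=combo_seed,
                )
                sub = out / variant / f"T{temp:g}_x{factor:g}"
                sub.mkdir(parents=True, exist_ok=True)
                for tr in traces:
                    tr = dataclasses.replace(
                        tr, meta={**tr.meta, "variant": variant, "seed": combo_seed}
                    )
                    fname = sub / f"{tr.cell_id}.csv"
                    write_trace_csv(tr, fname)
                    rows.append(
                        {
                            "path": str(fname.relative_to(out)),
                            "variant": variant,
                            "temperature_C": float(temp),
                            "factor": float(factor),
                            "cell_id": tr.cell_id,
                            "seed": combo_seed,
                        }
                    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
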