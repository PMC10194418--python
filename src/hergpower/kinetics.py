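"""hERG (IKr) gating model: rate laws, Q10 temperature scaling, variants.

The macroscopic current is modelled Hodgkin–Huxley style as

    I_hERG(t) = g_max · a(t) · i(t) · (V(t) − E_rev)

with a slow activation gate ``a`` and a fast inactivation gate ``i``, each
obeying  dx/dt = α(V)(1−x) − β(V)x  with single-exponential voltage-dependent
rates r(V) = A·exp(B·V).  Every rate and the conductance carries its own Q10,
so the model can be re-expressed at any recording temperature via

    rate(T) = rate(T_ref) · Q10^((T − T_ref)/10).

Pathogenic variants are phenomenological presets: conductance scaling,
per-process rate scaling, and a voltage shift of the inactivation gate.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "RateLaw",
    "GateKinetics",
    "GatingModel",
    "VariantPreset",
    "default_wt_model",
    "variant_presets",
    "scale_for_temperature",
    "apply_variant",
]

PROCESSES = ("activation", "deactivation", "inactivation", "recovery")

#: Guard band (°C) against Q10 extrapolation far outside the measured range.
TEMPERATURE_RANGE = (15.0, 40.0)


@dataclass(frozen=True)
class RateLaw:
    """Single-exponential voltage dependence r(V) = a·exp(b·V).

    ``a`` is the rate at 0 mV in ms⁻¹ (must be positive); ``b`` in mV⁻¹ is
    signed — positive for depolarization-activated rates, negative for
    hyperpolarization-activated ones.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("rate prefactor a must be > 0")

    def __call__(self, v):
        return self.a * np.exp(self.b * np.asarray(v, dtype=float))

    def scaled(self, factor: float) -> "RateLaw":
        return RateLaw(self.a * factor, self.b)


@dataclass(frozen=True)
class GateKinetics:
    """One gate's opening (alpha) and closing (beta) rate laws.

    ``v_offset`` shifts the gate's whole voltage dependence: rates are
    evaluated at V − v_offset, so a positive offset moves steady-state and
    time-constant curves toward depolarized potentials.
    """

    alpha: RateLaw
    beta: RateLaw
    v_offset: float = 0.0

    def rates(self, v):
        va = np.asarray(v, dtype=float) - self.v_offset
        return self.alpha(va), self.beta(va)

    def steady_state(self, v):
        al, be = self.rates(v)
        return al / (al + be)

    def time_constant(self, v):
        al, be = self.rates(v)
        return 1.0 / (al + be)


@dataclass(frozen=True)
class GatingModel:
    """Complete hERG channel parameterization at one reference temperature.

    Open probability is a^p · i with ``activation_exponent`` p: hERG opens
    through a chain of closed states, so macroscopic activation has a
    sigmoidal onset that a first-order gate cannot produce; raising the gate
    to a small integer power is the classical Hodgkin–Huxley device for that
    delay.
    """

    activation: GateKinetics
    inactivation: GateKinetics
    g_max: float  # nS (or nS/pF when density-normalized)
    e_rev: float  # mV
    t_ref: float  # °C
    q10_conductance: float
    q10_rates: Mapping[str, float] = field(
        default_factory=lambda: dict.fromkeys(PROCESSES, 2.2)
    )
    activation_exponent: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if not self.q10_conductance > 0:
            raise ValueError("q10_conductance must be > 0")
        missing = set(PROCESSES) - set(self.q10_rates)
        if missing:
            raise ValueError(f"q10_rates missing processes: {sorted(missing)}")
        if any(not q > 0 for q in self.q10_rates.values()):
            raise ValueError("all Q10 values must be > 0")
        # rates must stay finite and positive over the physiological range
        vgrid = np.linspace(-120.0, 60.0, 7)
        for gate in (self.activation, self.inactivation):
            al, be = gate.rates(vgrid)
            if not (np.all(np.isfinite(al)) and np.all(np.isfinite(be))):
                raise ValueError("rates must be finite over [-120, 60] mV")

    def open_probability(self, a, i):
        return np.asarray(a) ** self.activation_exponent * np.asarray(i)

    def current(self, a, i, v):
        """Macroscopic current in pA given gate values and voltage (mV)."""
        return self.g_max * self.open_probability(a, i) * (np.asarray(v) - self.e_rev)

    def with_uniform_q10(self, q_rates: float, q_conductance: float | None = None) -> "GatingModel":
        """Copy of the model with one Q10 for all four rates (and optionally g)."""
        return dataclasses.replace(
            self,
            q10_rates=dict.fromkeys(PROCESSES, q_rates),
            q10_conductance=self.q10_conductance if q_conductance is None else q_conductance,
        )


@dataclass(frozen=True)
class VariantPreset:
    """Phenomenological variant modifier relative to wild type."""

    name: str
    conductance_scale: float = 1.0
    rate_scales: Mapping[str, float] = field(
        default_factory=lambda: dict.fromkeys(PROCESSES, 1.0)
    )
    inactivation_vhalf_shift: float = 0.0  # mV, positive = depolarizing shift

    def __post_init__(self) -> None:
        if self.conductance_scale < 0:
            raise ValueError("conductance_scale must be >= 0")
        if any(not s > 0 for s in self.rate_scales.values()):
            raise ValueError("rate_scales values must be > 0")


@lru_cache(maxsize=1)
def _load_constants() -> dict:
    path = resources.files("hergpower.data").joinpath("default_model.toml")
    with path.open("rb") as fh:
        return tomllib.load(fh)


def _gate_from_dict(d: Mapping) -> GateKinetics:
    return GateKinetics(
        alpha=RateLaw(*d["alpha"]),
        beta=RateLaw(*d["beta"]),
        v_offset=float(d.get("v_offset", 0.0)),
    )


def model_from_dict(doc: Mapping) -> GatingModel:
    """Build a GatingModel from a parsed TOML/JSON ``[model]`` table."""
    m = doc["model"] if "model" in doc else doc
    return GatingModel(
        activation=_gate_from_dict(m["activation"]),
        inactivation=_gate_from_dict(m["inactivation"]),
        g_max=float(m["g_max"]),
        e_rev=float(m["e_rev"]),
        t_ref=float(m["t_ref"]),
        q10_conductance=float(m["q10_conductance"]),
        q10_rates={k: float(v) for k, v in m["q10_rates"].items()},
        activation_exponent=int(m.get("activation_exponent", 1)),
        label=str(m.get("label", "")),
    )


def model_to_dict(model: GatingModel) -> dict:
    """Serialize a model to the ``[model]`` document structure (TOML/JSON-ready).

    Round-trips through :func:`model_from_dict`.
    """
    return {
        "model": {
            "label": model.label,
            "g_max": model.g_max,
            "e_rev": model.e_rev,
            "t_ref": model.t_ref,
            "q10_conductance": model.q10_conductance,
            "activation_exponent": model.activation_exponent,
            "q10_rates": dict(model.q10_rates),
            "activation": {
                "alpha": [model.activation.alpha.a, model.activation.alpha.b],
                "beta": [model.activation.beta.a, model.activation.beta.b],
                "v_offset": model.activation.v_offset,
            },
            "inactivation": {
                "alpha": [model.inactivation.alpha.a, model.inactivation.alpha.b],
                "beta": [model.inactivation.beta.a, model.inactivation.beta.b],
                "v_offset": model.inactivation.v_offset,
            },
        }
    }


def default_wt_model() -> GatingModel:
    """The packaged wild-type hERG model at 37°C (versioned constants file)."""
    return model_from_dict(_load_constants())


def variant_presets() -> dict[str, VariantPreset]:
    """Packaged presets: WT (identity), R328C (loss), D591H (gain)."""
    doc = _load_constants()
    out = {}
    for name, d in doc["variants"].items():
        out[name] = VariantPreset(
            name=name,
            conductance_scale=float(d["conductance_scale"]),
            rate_scales={k: float(v) for k, v in d["rate_scales"].items()},
            inactivation_vhalf_shift=float(d["inactivation_vhalf_shift"]),
        )
    return out


def scale_for_temperature(model: GatingModel, temperature: float) -> GatingModel:
    """Re-express the model at ``temperature`` via per-process Q10 scaling.

    Each rate is multiplied by its process Q10 raised to (T − t_ref)/10, the
    conductance by q10_conductance likewise; the result's t_ref is the new
    temperature, so scaling is transitive.
    """
    lo, hi = TEMPERATURE_RANGE
    if not (lo <= temperature <= hi):
        raise ValueError(f"temperature {temperature} outside supported range [{lo}, {hi}] °C")
    dt10 = (temperature - model.t_ref) / 10.0
    if dt10 == 0.0:
        return model

    def f(process: str) -> float:
        return model.q10_rates[process] ** dt10

    act = dataclasses.replace(
        model.activation,
        alpha=model.activation.alpha.scaled(f("activation")),
        beta=model.activation.beta.scaled(f("deactivation")),
    )
    inact = dataclasses.replace(
        model.inactivation,
        alpha=model.inactivation.alpha.scaled(f("recovery")),
        beta=model.inactivation.beta.scaled(f("inactivation")),
    )
    return dataclasses.replace(
        model,
        activation=act,
        inactivation=inact,
        g_max=model.g_max * model.q10_conductance**dt10,
        t_ref=temperature,
    )


def apply_variant(model: GatingModel, preset: VariantPreset) -> GatingModel:
    """Apply a variant preset: conductance scale, rate scales, inactivation shift."""
    rs = dict.fromkeys(PROCESSES, 1.0) | dict(preset.rate_scales)
    act = dataclasses.replace(
        model.activation,
        alpha=model.activation.alpha.scaled(rs["activation"]),
        beta=model.activation.beta.scaled(rs["deactivation"]),
    )
    inact = dataclasses.replace(
        model.inactivation,
        alpha=model.inactivation.alpha.scaled(rs["recovery"]),
        beta=model.inactivation.beta.scaled(rs["inactivation"]),
        v_offset=model.inactivation.v_offset + preset.inactivation_vhalf_shift,
    )
    label = f"{model.label}+{preset.name}" if preset.name != "WT" else model.label
    return dataclasses.replace(
        model,
        activation=act,
        inactivation=inact,
        g_max=model.g_max * preset.conductance_scale,
        label=label,
    )
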