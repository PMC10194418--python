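"""Ventricular action-potential clamp command waveforms and time dilation.

The AP-clamp protocol drives a voltage-clamped cell with an action-potential
shaped command instead of rectangular steps, so that the recorded hERG current
reflects the channel's contribution during a physiological voltage trajectory.
Slowing ("dilating") the time axis of the command by a factor f compensates,
at room temperature, for the slower channel kinetics relative to 37°C.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["VoltageProtocol", "APShapeParams", "build_ap_waveform", "dilate"]


class ProtocolValidationError(ValueError):
    """Raised when a protocol or its shape parameters violate an invariant."""


@dataclass(frozen=True)
class VoltageProtocol:
    """A sampled time→voltage command waveform.

    Parameters
    ----------
    times : ndarray
        Sample times in milliseconds, strictly increasing from 0.
    voltages : ndarray
        Command voltage in millivolts at each sample; the waveform starts and
        ends at ``holding_potential``.
    holding_potential : float
        Holding voltage in mV between sweeps.
    dilation_factor : float
        Cumulative time-dilation factor already applied to this waveform
        (1.0 for the standard protocol).
    label : str
        Free-text description.
    """

    times: np.ndarray
    voltages: np.ndarray
    holding_potential: float
    dilation_factor: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v) or len(t) < 2:
            raise ProtocolValidationError(
                "times/voltages must be 1-D, equal length and have >= 2 samples"
            )
        if t[0] != 0.0:
            raise ProtocolValidationError("times must start at 0 (field: times)")
        if not np.all(np.diff(t) > 0):
            raise ProtocolValidationError("times must be strictly increasing (field: times)")
        if v[0] != self.holding_potential or v[-1] != self.holding_potential:
            raise ProtocolValidationError(
                "voltages must start and end at holding_potential (field: voltages)"
            )
        if not self.dilation_factor > 0:
            raise ProtocolValidationError("dilation_factor must be > 0 (field: dilation_factor)")

    @property
    def duration(self) -> float:
        """Total waveform duration in ms."""
        return float(self.times[-1])


@dataclass(frozen=True)
class APShapeParams:
    """Parameters of the simplified human ventricular AP command shape.

    The defaults describe a standard human ventricular envelope: hold −80 mV,
    rapid 2 ms upstroke to +40 mV, a +20 mV plateau and repolarization that is
    90% complete near ``apd90`` milliseconds after the upstroke begins.
    """

    holding_potential: float = -80.0  # mV
    peak_voltage: float = 40.0  # mV
    upstroke_duration: float = 2.0  # ms
    plateau_voltage: float = 20.0  # mV
    apd90: float = 300.0  # ms, upstroke start to ~90% repolarization
    repolarization_shape: str = "spline"  # "linear" or "spline"
    pre_hold: float = 100.0  # ms
    post_hold: float = 100.0  # ms
    sample_interval: float = 0.5  # ms

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ProtocolValidationError("sample_interval must be > 0 (field: sample_interval)")
        if not (self.apd90 > self.upstroke_duration > 0):
            raise ProtocolValidationError(
                "apd90 must exceed upstroke_duration, both > 0 (fields: apd90, upstroke_duration)"
            )
        if self.pre_hold < 0 or self.post_hold < 0:
            raise ProtocolValidationError("pre_hold/post_hold must be >= 0 (fields: pre_hold, post_hold)")
        if not (self.peak_voltage > self.plateau_voltage > self.holding_potential):
            raise ProtocolValidationError(
                "need peak_voltage > plateau_voltage > holding_potential "
                "(fields: peak_voltage, plateau_voltage, holding_potential)"
            )
        if self.repolarization_shape not in ("linear", "spline"):
            raise ProtocolValidationError(
                "repolarization_shape must be 'linear' or 'spline' (field: repolarization_shape)"
            )


def _repolarization_curve(params: APShapeParams) -> PchipInterpolator:
    """Monotone-decaying voltage curve from the AP peak back to hold.

    Anchored at control points expressed as fractions of the repolarization
    span; PCHIP keeps the decay shape-preserving (no overshoot).  The curve
    crosses 90% repolarization at ~94% of the span and reaches full hold at
    the end, so ``apd90`` is a nominal (slightly conservative) APD90.
    """
    hold, peak, plateau = params.holding_potential, params.peak_voltage, params.plateau_voltage
    v90 = hold + 0.1 * (peak - hold)
    drop = plateau - v90
    fractions = np.array([0.0, 0.08, 0.35, 0.60, 0.80, 0.94, 1.0])
    anchors = np.array(
        [
            peak,
            plateau + 0.1 * (peak - plateau),
            plateau,
            plateau - 0.45 * drop,
            plateau - 0.85 * drop,
            v90,
            hold,
        ]
    )
    span = params.apd90 - params.upstroke_duration
    return PchipInterpolator(params.upstroke_duration + fractions * span, anchors)


def build_ap_waveform(params: APShapeParams) -> VoltageProtocol:
    """Construct the standard (factor-1) AP-clamp command waveform.

    The waveform is hold → linear upstroke → repolarization back to hold,
    followed by ``post_hold`` at the holding potential.  Total duration is
    ``pre_hold + apd90 + post_hold`` up to one sample of rounding.
    """
    total = params.pre_hold + params.apd90 + params.post_hold
    n = int(round(total / params.sample_interval))
    times = np.arange(n + 1) * params.sample_interval
    t_ap = times - params.pre_hold  # time since upstroke start

    v = np.full_like(times, params.holding_potential)
    up = (t_ap > 0) & (t_ap <= params.upstroke_duration)
    v[up] = params.holding_potential + (
        params.peak_voltage - params.holding_potential
    ) * t_ap[up] / params.upstroke_duration

    repol = (t_ap > params.upstroke_duration) & (t_ap < params.apd90)
    if params.repolarization_shape == "spline":
        v[repol] = _repolarization_curve(params)(t_ap[repol])
    else:
        # linear: peak → plateau over the first 8% of the span, then to hold
        span = params.apd90 - params.upstroke_duration
        knee = params.upstroke_duration + 0.08 * span
        s = t_ap[repol]
        early = s <= knee
        v_rep = np.empty_like(s)
        v_rep[early] = params.peak_voltage + (params.plateau_voltage - params.peak_voltage) * (
            s[early] - params.upstroke_duration
        ) / (knee - params.upstroke_duration)
        v_rep[~early] = params.plateau_voltage + (
            params.holding_potential - params.plateau_voltage
        ) * (s[~early] - knee) / (params.apd90 - knee)
        v[repol] = v_rep

    v[0] = params.holding_potential
    v[-1] = params.holding_potential
    return VoltageProtocol(
        times=times,
        voltages=v,
        holding_potential=params.holding_potential,
        dilation_factor=1.0,
        label=f"AP apd90={params.apd90:g}ms {params.repolarization_shape}",
    )


def dilate(protocol: VoltageProtocol, factor: float) -> VoltageProtocol:
    """Stretch the protocol's time axis uniformly by ``factor``.

    Voltages are untouched; only sample times scale, so the command visits the
    same voltage sequence more slowly (factor > 1) or faster (factor < 1).
    """
    if not factor > 0:
        raise ProtocolValidationError("dilation factor must be > 0")
    if factor == 1.0:
        return protocol
    return dataclasses.replace(
        protocol,
        times=protocol.times * factor,
        dilation_factor=protocol.dilation_factor * factor,
        label=protocol.label,
    )
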