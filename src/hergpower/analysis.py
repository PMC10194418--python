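"""Repolarization power, the dilation correction, and factor selection.

The repolarization power is the time integral of the hERG current developed
during an AP clamp (pA·s, or pA/pF·s for density-normalized traces).  A
recording made under a time-dilated AP (factor f) is brought back to the
reference time base by dividing time by f and multiplying current by f; that
correction leaves the time integral unchanged, which is what lets a slowed
room-temperature protocol predict the 37°C repolarization power.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import GatingModel, scale_for_temperature
from .protocol import VoltageProtocol, dilate
from .simulate import CurrentTrace, simulate_current

__all__ = [
    "RepowerResult",
    "FactorScanResult",
    "repolarization_power",
    "correct_trace",
    "time_of_peak",
    "normalize_to_peak",
    "trace_discrepancy",
    "scan_factors",
    "blank_late_artifact",
]


@dataclass(frozen=True)
class RepowerResult:
    """Repolarization power with its integration window and provenance."""

    value: float  # pA·s, or pA/pF·s when density_normalized
    window_start: float  # ms
    window_end: float  # ms
    trace_id: str = ""
    density_normalized: bool = False


@dataclass(frozen=True)
class FactorScanResult:
    """Corrected repolarization power per dilation factor vs a reference."""

    factors: tuple
    repower_by_factor: dict
    reference_repower: float
    discrepancy_by_factor: dict
    best_factor: float
    rms_by_factor: dict = field(default_factory=dict)
    reference_temperature: float = float("nan")
    room_temperature: float = float("nan")


def repolarization_power(
    trace: CurrentTrace,
    window_start: float | None = None,
    window_end: float | None = None,
) -> RepowerResult:
    """Trapezoidal time integral of the current over [window_start, window_end].

    Defaults to the trace's full span.  Negative excursions (leak, the late
    inward contamination) integrate with their sign, as recorded currents are
    integrated as-is.  Result is in pA·s (ms×pA / 1000).
    """
    t, c = trace.times, trace.current
    w0 = float(t[0]) if window_start is None else float(window_start)
    w1 = float(t[-1]) if window_end is None else float(window_end)
    if not (w1 > w0):
        raise ValueError("window_end must exceed window_start")
    if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
        raise ValueError(
            f"window [{w0}, {w1}] outside trace span [{t[0]}, {t[-1]}]"
        )
    inside = (t > w0) & (t < w1)
    tt = np.concatenate(([w0], t[inside], [w1]))
    cc = np.concatenate(([np.interp(w0, t, c)], c[inside], [np.interp(w1, t, c)]))
    value = float(np.trapezoid(cc, tt)) / 1000.0
    return RepowerResult(
        value=value,
        window_start=w0,
        window_end=w1,
        trace_id=trace.cell_id,
        density_normalized=trace.density_normalized,
    )


def correct_trace(trace: CurrentTrace, factor: float) -> CurrentTrace:
    """Undo a time dilation: divide time by ``factor``, multiply current by it.

    The substitution t = f·s makes the corrected trace's integral equal the
    raw integral of the dilated recording, so correction is integral-
    preserving by construction.
    """
    if not factor > 0:
        raise ValueError("correction factor must be > 0")
    if not np.isclose(trace.dilation_factor, factor):
        warnings.warn(
            f"correcting with factor {factor} but trace records dilation "
            f"{trace.dilation_factor}",
            stacklevel=2,
        )
    meta = dict(trace.meta)
    meta["corrected_with_factor"] = factor
    return dataclasses.replace(
        trace,
        times=trace.times / factor,
        current=trace.current * factor,
        dilation_factor=trace.dilation_factor / factor,
        meta=meta,
    )


def time_of_peak(trace: CurrentTrace) -> float:
    """Time (ms) of the maximum current sample; earliest sample wins ties.

    A flat trace has no meaningful peak: the start time is returned with a
    degenerate-peak warning.
    """
    c = trace.current
    if np.all(c == c[0]):
        warnings.warn("degenerate peak: trace is constant", stacklevel=2)
        return float(trace.times[0])
    return float(trace.times[int(np.argmax(c))])


def normalize_to_peak(trace: CurrentTrace) -> CurrentTrace:
    """Scale the current to a unit maximum (profile-shape comparison)."""
    peak = float(np.max(trace.current))
    if not peak > 0:
        raise ValueError("cannot normalize: maximum current is not positive")
    meta = dict(trace.meta)
    meta["normalized_to_peak"] = True
    return dataclasses.replace(trace, current=trace.current / peak, meta=meta)


def trace_discrepancy(a: CurrentTrace, b: CurrentTrace) -> float:
    """RMS difference (pA) between two traces over their overlapping span.

    Both traces are linearly resampled onto a uniform grid at the finer of
    the two native sampling intervals before differencing.
    """
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if not hi > lo:
        raise ValueError("traces have no overlapping time span")
    dt = min(float(np.median(np.diff(a.times))), float(np.median(np.diff(b.times))))
    n = max(int(np.ceil((hi - lo) / dt)), 2)
    grid = np.linspace(lo, hi, n + 1)
    ra = np.interp(grid, a.times, a.current)
    rb = np.interp(grid, b.times, b.current)
    return float(np.sqrt(np.mean((ra - rb) ** 2)))


def blank_late_artifact(
    trace: CurrentTrace, terminal_fraction: float = 0.3, threshold: float = 0.0
) -> CurrentTrace:
    """Zero negative current below ``threshold`` in the terminal sweep fraction.

    Optional cleanup of the late inward contamination current; integration of
    recorded traces keeps the artifact by default.
    """
    t = trace.times
    onset = t[0] + (1.0 - terminal_fraction) * (t[-1] - t[0])
    c = trace.current.copy()
    mask = (t >= onset) & (c < threshold)
    c[mask] = 0.0
    meta = dict(trace.meta)
    meta["late_artifact_blanked"] = True
    return dataclasses.replace(trace, current=c, meta=meta)


def scan_factors(
    model: GatingModel,
    protocol: VoltageProtocol,
    t_reference: float,
    t_room: float,
    factors,
    solver_reltol: float = 1e-8,
    solver_abstol: float = 1e-10,
    capacitance_pF: float | None = None,
) -> FactorScanResult:
    """Select the dilation factor whose corrected room-temperature power best
    matches the reference-temperature repolarization power.

    The reference is simulated at ``t_reference`` under the undilated
    protocol.  For each factor f the model is expressed at ``t_room``,
    simulated under the f-dilated protocol, corrected (time ÷ f, current × f)
    and integrated.  The factor minimizing the absolute discrepancy wins;
    ties go to the smaller factor.  ``capacitance_pF`` divides all currents
    (density normalization) and cannot change the selection.
    """
    factors = tuple(sorted(float(f) for f in factors))
    if any(not f > 0 for f in factors):
        raise ValueError("all factors must be > 0")

    def density(tr: CurrentTrace) -> CurrentTrace:
        if capacitance_pF is None:
            return tr
        return dataclasses.replace(
            tr, current=tr.current / capacitance_pF, density_normalized=True
        )

    ref_model = scale_for_temperature(model, t_reference)
    ref_trace = density(simulate_current(ref_model, protocol, solver_reltol, solver_abstol))
    ref_rp = repolarization_power(ref_trace).value

    room_model = scale_for_temperature(model, t_room)
    repower_by_factor: dict[float, float] = {}
    discrepancy: dict[float, float] = {}
    rms: dict[float, float] = {}
    best_factor = None
    best_disc = np.inf
    for f in factors:
        raw = density(
            simulate_current(room_model, dilate(protocol, f), solver_reltol, solver_abstol)
        )
        corrected = correct_trace(raw, f)
        rp = repolarization_power(corrected).value
        repower_by_factor[f] = rp
        disc = abs(rp - ref_rp)
        discrepancy[f] = disc
        rms[f] = trace_discrepancy(corrected, ref_trace)
        if disc < best_disc:  # strict: ties keep the smaller (earlier) factor
            best_disc = disc
            best_factor = f
    return FactorScanResult(
        factors=factors,
        repower_by_factor=repower_by_factor,
        reference_repower=ref_rp,
        discrepancy_by_factor=discrepancy,
        best_factor=float(best_factor),
        rms_by_factor=rms,
        reference_temperature=t_reference,
        room_temperature=t_room,
    )
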