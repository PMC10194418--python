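"""Whole-cell hERG current simulation under an AP clamp.

Integrates the two gating ODEs along a voltage protocol and evaluates the
macroscopic current on the protocol's own sample grid.  This is the package's
synthetic-data generator: populations of cells differ in maximal conductance
(log-normal, mean-preserving), and recorded traces can be degraded with
Gaussian noise, ohmic leak and the small late inward contamination current
seen on automated patch-clamp systems when the intracellular solution is
contaminated by extracellular Tyrode during the cell-catch step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import GatingModel
from .protocol import VoltageProtocol

__all__ = [
    "CurrentTrace",
    "ArtifactParams",
    "simulate_current",
    "simulate_gates",
    "add_artifacts",
    "simulate_population",
]


class SolverError(RuntimeError):
    """ODE integration failed; carries the time point reached."""

    def __init__(self, message: str, t_failed: float):
        super().__init__(f"{message} (integration stopped at t = {t_failed:g} ms)")
        self.t_failed = t_failed


@dataclass(frozen=True)
class CurrentTrace:
    """A sampled current recording or simulation.

    ``current`` is in pA, or pA/pF when ``density_normalized`` is set.
    ``meta`` carries provenance (seed, model label, variant, ...).
    """

    times: np.ndarray  # ms, strictly increasing
    current: np.ndarray
    temperature: float  # °C
    dilation_factor: float
    cell_id: str = ""
    density_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", c)
        if t.ndim != 1 or len(t) != len(c) or len(t) < 2:
            raise ValueError("times/current must be 1-D, equal length, >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.dilation_factor > 0:
            raise ValueError("dilation_factor must be positive")


@dataclass(frozen=True)
class ArtifactParams:
    """Recording-artifact model: noise, leak, late inward contamination."""

    noise_sd: float = 0.0  # pA
    leak_conductance: float = 0.0  # nS
    leak_reversal: float = 0.0  # mV
    contamination_amplitude: float = 0.0  # pA, magnitude of the late inward component
    contamination_onset_fraction: float = 0.7  # of total duration, in (0, 1]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.leak_conductance < 0:
            raise ValueError("noise_sd and leak_conductance must be >= 0")
        if not (0 < self.contamination_onset_fraction <= 1):
            raise ValueError("contamination_onset_fraction must be in (0, 1]")


def simulate_gates(
    model: GatingModel,
    protocol: VoltageProtocol,
    solver_reltol: float = 1e-8,
    solver_abstol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the activation and inactivation gates along the protocol.

    Gates start at their steady state for the holding potential (cells sit at
    hold between sweeps).  Voltage between samples is linearly interpolated.
    Returns (a, i) sampled on the protocol grid.

    The gate ODEs do not involve the conductance, so one gating solution
    serves every cell of a population that differs only in g_max.
    """
    t = protocol.times
    v_arr = protocol.voltages
    a0 = float(model.activation.steady_state(protocol.holding_potential))
    i0 = float(model.inactivation.steady_state(protocol.holding_potential))

    def rhs(s, y):
        v = np.interp(s, t, v_arr)
        al_a, be_a = model.activation.rates(v)
        al_i, be_i = model.inactivation.rates(v)
        a, i = y
        return (al_a * (1.0 - a) - be_a * a, al_i * (1.0 - i) - be_i * i)

    # cap the step so short protocol features (the 2 ms upstroke) are seen
    max_step = max(protocol.duration / 250.0, float(np.min(np.diff(t))))
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        (a0, i0),
        method="LSODA",
        t_eval=t,
        rtol=solver_reltol,
        atol=solver_abstol,
        max_step=max_step,
    )
    if not sol.success:
        raise SolverError(f"gating ODE solver failed: {sol.message}", float(sol.t[-1]) if len(sol.t) else t[0])
    a, i = sol.y
    return np.clip(a, 0.0, 1.0), np.clip(i, 0.0, 1.0)


def simulate_current(
    model: GatingModel,
    protocol: VoltageProtocol,
    solver_reltol: float = 1e-8,
    solver_abstol: float = 1e-10,
    cell_id: str = "",
) -> CurrentTrace:
    """Simulate the whole-cell hERG current evoked by ``protocol``.

    The model must already be expressed at the intended recording temperature
    (apply :func:`~hergpower.kinetics.scale_for_temperature` first); the
    trace records ``model.t_ref`` as its temperature.
    """
    a, i = simulate_gates(model, protocol, solver_reltol, solver_abstol)
    current = model.current(a, i, protocol.voltages)
    return CurrentTrace(
        times=protocol.times.copy(),
        current=current,
        temperature=model.t_ref,
        dilation_factor=protocol.dilation_factor,
        cell_id=cell_id,
        meta={
            "model": model.label,
            "solver_reltol": solver_reltol,
            "solver_abstol": solver_abstol,
        },
    )


def _contamination_ramp(times: np.ndarray, onset_fraction: float) -> np.ndarray:
    """Smoothstep ramp 0→1 over the terminal fraction of the sweep."""
    t0, t1 = times[0], times[-1]
    onset = t0 + onset_fraction * (t1 - t0)
    if onset >= t1:
        return np.zeros_like(times)
    s = np.clip((times - onset) / (t1 - onset), 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def add_artifacts(
    trace: CurrentTrace, params: ArtifactParams, protocol: VoltageProtocol
) -> CurrentTrace:
    """Overlay recording artifacts on a clean simulated trace.

    Adds seeded Gaussian noise, ohmic leak g_leak·(V − E_leak), and an inward
    (negative) contamination component that ramps in smoothly over the
    terminal part of the sweep.  With all parameters zero the trace is
    returned unchanged.
    """
    if len(trace.times) != len(protocol.times) or not np.allclose(
        trace.times, protocol.times
    ):
        raise ValueError("trace and protocol must share the same time grid")
    if (
        params.noise_sd == 0
        and params.leak_conductance == 0
        and params.contamination_amplitude == 0
    ):
        return trace
    current = trace.current.copy()
    if params.leak_conductance > 0:
        current += params.leak_conductance * (protocol.voltages - params.leak_reversal)
    if params.contamination_amplitude != 0:
        ramp = _contamination_ramp(trace.times, params.contamination_onset_fraction)
        current -= abs(params.contamination_amplitude) * ramp
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.rng_seed)
        current += rng.normal(0.0, params.noise_sd, size=current.shape)
    meta = dict(trace.meta)
    meta["artifact_seed"] = params.rng_seed
    meta["noise_sd"] = params.noise_sd
    return dataclasses.replace(trace, current=current, meta=meta)


def simulate_population(
    model: GatingModel,
    protocol: VoltageProtocol,
    n_cells: int,
    conductance_cv: float,
    artifacts: ArtifactParams | None = None,
    rng_seed: int = 0,
    solver_reltol: float = 1e-8,
    solver_abstol: float = 1e-10,
) -> list[CurrentTrace]:
    """Simulate ``n_cells`` cells differing in maximal conductance.

    Per-cell g_max is drawn from a log-normal parameterized to have mean
    ``model.g_max`` and coefficient of variation ``conductance_cv`` (so the
    population mean current is unbiased).  The gating solution is computed
    once and shared — exact, since the gates are conductance-independent.
    Per-cell artifact seeds derive deterministically from ``rng_seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if conductance_cv < 0:
        raise ValueError("conductance_cv must be >= 0")
    a, i = simulate_gates(model, protocol, solver_reltol, solver_abstol)
    base = model.open_probability(a, i) * (protocol.voltages - model.e_rev)

    rng = np.random.default_rng(rng_seed)
    if conductance_cv > 0:
        sigma = np.sqrt(np.log1p(conductance_cv**2))
        mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_cells))
    else:
        mult = np.ones(n_cells)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n_cells)

    traces = []
    for k in range(n_cells):
        tr = CurrentTrace(
            times=protocol.times.copy(),
            current=model.g_max * mult[k] * base,
            temperature=model.t_ref,
            dilation_factor=protocol.dilation_factor,
            cell_id=f"cell{k:03d}",
            meta={
                "model": model.label,
                "population_seed": rng_seed,
                "g_multiplier": float(mult[k]),
            },
        )
        if artifacts is not None:
            tr = add_artifacts(
                tr, dataclasses.replace(artifacts, rng_seed=int(cell_seeds[k])), protocol
            )
        traces.append(tr)
    return traces
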