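# Methods

## The index and the correction

The repolarization power of a trace is the trapezoidal time integral of the
recorded current over an explicit window (default: the full sweep, including
the pre/post-hold segments, whose contribution is ≈ 0 for clean traces; the
window is stored in every result so users can restrict it, which matters for
leaky recordings). Negative excursions — leak, the late inward contamination
current of automated patch systems — integrate with their sign: recorded
currents are integrated as plotted. An optional `blank_late_artifact` step
zeroes negative current in the terminal sweep fraction; it is off by default.

A recording made under an f-fold time-dilated command is corrected by
dividing time by f and multiplying current by f. By the substitution t = f·s
this leaves the integral identical to the raw integral of the dilated
recording — the correction changes the time base and amplitude, never the
index. Factor selection therefore reduces to finding the dilation whose raw
integral at room temperature equals the reference integral; the scan
nevertheless reports corrected traces so that shape overlap (RMS discrepancy
on a common grid, linear interpolation at the finer native sampling) can be
inspected alongside. Selection minimizes the absolute repower discrepancy;
ties go to the smaller factor (shorter protocols are experimentally cheaper).
RMS discrepancy is reported but never drives selection. The scan is invariant
to density normalization (dividing all currents by a capacitance cannot
change the argmin).

## AP command waveform

No standardized digitized command is bundled; the builder produces a
parametric human-ventricular envelope: hold −80 mV, linear 2 ms upstroke to
+40 mV, brief decay to a +20 mV plateau, then a shape-preserving monotone
(PCHIP) repolarization anchored so that 90% repolarization (−68 mV) falls at
~94% of the nominal APD90 (default 300 ms) and the hold is reached at APD90
exactly; 100 ms pre/post-hold, 0.5 ms sampling. A piecewise-linear
alternative (`repolarization_shape="linear"`) and CSV import
(`read_protocol_csv`) let users substitute their own digitized waveform —
all analyses are waveform-agnostic. Dilation stretches the entire command
(holds included) uniformly; hold segments contribute ≈ 0 to integrals, so
this choice is inert. Times are milliseconds throughout; powers are reported
in pA·s (pA/pF·s when density-normalized).

## Gating model

I = g_max · a⁴ · i · (V − E_rev), two independent gates with
dx/dt = α(V)(1−x) − β(V)x and r(V) = A·e^{BV} (A > 0; B signed). Defaults
(37°C, `src/hergpower/data/default_model.toml`, versioned):

| quantity | value | note |
|---|---|---|
| activation α | 7.0e-4·e^{0.07V} ms⁻¹ | τ_act(+20 mV) ≈ 350 ms |
| deactivation β | 2.27e-4·e^{−0.03V} ms⁻¹ | τ_deact(−80 mV) ≈ 400 ms |
| recovery α_i | 1.0e-2·e^{−0.02V} ms⁻¹ | τ_rec(−40 mV) ≈ 33 ms |
| inactivation β_i | 3.0e-1·e^{0.09V} ms⁻¹ | sub-ms at the plateau |
| g_max | 500 nS (effective) | see below |
| E_rev | −88 mV | physiological K⁺ gradient |
| Q10, each rate | 2.2 | uniform; overridable per process |
| Q10, conductance | 1.4 | |
| activation exponent | 4 | sigmoidal activation onset |

Design choices that were genuinely open, and how they were made:

- **HH gates, not a Markov chain.** Every analysis depends only on the
  macroscopic current; the model interface (gates → open probability →
  current) permits a Markov drop-in later.
- **Fourth-power activation.** hERG opens through several closed states, so
  macroscopic activation is sigmoidal. Beyond realism this is structural: a
  first-order activation gate makes the corrected integral grow at most
  quadratically in the dilation factor around the matched point, which pins
  the discrepancy-minimizing factor near (1.4·2.2²)^⅓ ≈ 1.9 and leaves an
  irreducible ~18% error at factor 2 — inconsistent with the observed
  corrected-trace overlap. The a⁴ form restores the observed selection of 2
  with a residual of a few percent.
- **Slow-kinetics regime.** Prefactors put activation and recovery far from
  quasi-static equilibrium during a 300 ms AP (τ_act at the plateau and
  τ_deact at hold of several hundred ms — the slow end of reported hERG
  values). In the quasi-static regime temperature compensation by time
  dilation would be unnecessary and small factors would always win; the slow
  regime is the one the method exists for, and the packaged constants were
  calibrated, once, so that the simulated 10°C temperature deficit is
  compensated by the empirically observed factor of 2. The simulator
  consequently *exaggerates* the absolute temperature sensitivity of the
  integral (22.5 → 1.1 pA·s from 37°C to 27°C); real cells lose less. Treat
  cross-temperature magnitudes as qualitative.
- **Uniform Q10 2.2 default.** Measured gating-rate Q10s span 1.7–2.6 with no
  per-process assignment published; the midpoint is applied to all four
  rates. This is also the regime in which a single correction factor can be
  exact: if every rate and the conductance shared Q10 = q, cooling by ΔT with
  f = q^(−ΔT/10) would reproduce the reference trace *pointwise* (the
  time-rescaling identity, used as the package's central numerical oracle).
  Each process's Q10 is separately overridable in config.
- **g_max is an effective amplitude.** AP-clamp currents identify only
  g_max × gate occupancy; with the slow-kinetics defaults the peak open
  probability is ~10⁻², so g_max = 500 nS is a scale parameter, not a
  literal channel count × unitary conductance. It is set so the wild-type
  37°C repolarization power is ~22 pA·s, the order of magnitude of stable
  hERG lines under AP clamp.
- **Variant presets are phenomenological.** R328C: conductance ×0.3 (loss).
  D591H: +30 mV depolarizing shift of inactivation and recovery ×2 (gain;
  more current at plateau voltages). They reproduce the qualitative ordering
  R328C < WT < D591H and the late shift of the corrected D591H current, not
  any specific published biophysical parameter set.

## Simulation

Gates are integrated with LSODA (stiff-capable, adaptive) at rtol 1e-8 /
atol 1e-10, voltage linearly interpolated between protocol samples, the step
capped at duration/250 so short features (the 2 ms upstroke) are never
stepped over; gates start at their holding-potential steady state. Tenfold
tighter tolerances move the integral by < 10⁻⁴ relative. Solver failure
raises with the failing time point. Because the gate ODEs do not involve the
conductance, a population differing only in g_max shares one gating solution
exactly; per-cell conductances are log-normal, parameterized to have mean
g_max (so the cohort mean is unbiased) with a specified CV, and per-cell
seeds derive deterministically from the population seed.

Recording artifacts are additive and optional: seeded Gaussian noise; ohmic
leak g_leak·(V − E_leak); and an inward contamination component that ramps in
(smoothstep) over the terminal sweep fraction, mimicking the late inward
current seen on automated platforms when intracellular solution is
contaminated during cell catch. No quantitative description of that artifact
exists; amplitude and onset are placeholders whose purpose is robustness
testing of the analysis, and they are excluded from any headline number.

## What the synthetic data do and do not show

The generator emulates: Q10-governed slowing of gating and conductance,
cell-to-cell conductance spread, recording noise, leak, the late inward
artifact, and the variant phenotypes above. It does not emulate: seal/series
resistance errors and capacitive transients, trafficking or
temperature-dependent surface expression, sigmoidal-delay details beyond the
a⁴ approximation, drug block, or instrument-specific quantization. Passing
tests therefore demonstrate the internal consistency of the
dilation-correction method and its statistical detectability under realistic
noise and spread — not that any particular real cell line has these exact
kinetics.

## Statistics

Cohorts of 6–9 cells are summarized as mean ± SEM plus Tukey box statistics
(quartiles by linear interpolation; whiskers at the most extreme points
within 1.5×IQR fences; outliers listed). Comparisons default to
non-parametric rank tests — Wilcoxon signed-rank (zero-split for ties) when
paired, Mann–Whitney U otherwise — with t-tests selectable; stars follow
ns / * (p < 0.05) / ** (p < 0.01). Pairwise tests are uncorrected by default,
matching common practice for two or three planned comparisons at this scale.

## Numerical conventions and degenerate inputs

Integration windows may fall between samples (boundary values linearly
interpolated); a window outside the trace span is an error. `time_of_peak`
breaks ties toward the earliest sample and warns on constant traces
(returning the window start). `normalize_to_peak` requires a positive
maximum. `correct_trace` warns when the supplied factor disagrees with the
trace's recorded dilation. Trace comparison resamples both traces onto a
uniform grid at the finer of the two native sampling intervals. Temperature
scaling refuses to extrapolate outside 15–40°C.

## Problem sizes

Default sweeps are 1001 samples (0.5 ms over 500 ms); test and fixture
simulations use 1 ms sampling where the check is insensitive to the grid.
The statistical-pattern check runs 20 replicates of 9 cells × 3 conditions,
sharing gating solutions across cells, and completes in seconds. The fixture
generator's default grid (3 variants × 4 temperatures × 6 factors × 8 cells
= 576 traces) regenerates deterministically from its seed rather than being
shipped.
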