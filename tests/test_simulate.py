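import dataclasses

import numpy as np
import pytest

from hergpower import (
    ArtifactParams,
    VoltageProtocol,
    add_artifacts,
    correct_trace,
    dilate,
    repolarization_power,
    scale_for_temperature,
    simulate_current,
    simulate_population,
)


def constant_protocol(v, duration=200.0, dt=1.0):
    times = np.arange(0.0, duration + dt / 2, dt)
    return VoltageProtocol(
        times=times, voltages=np.full_like(times, v), holding_potential=v
    )


class TestSimulateCurrent:
    def test_zero_driving_force_gives_zero_current(self, wt_model):
        tr = simulate_current(wt_model, constant_protocol(wt_model.e_rev))
        assert np.max(np.abs(tr.current)) < 1e-9

    def test_closed_channel_at_hold(self, wt_model, wt37_trace):
        hold = simulate_current(wt_model, constant_protocol(-80.0))
        assert np.max(np.abs(hold.current)) < 0.01 * np.max(wt37_trace.current)

    def test_trace_carries_provenance(self, wt_model, protocol, wt37_trace):
        assert wt37_trace.temperature == 37.0
        assert wt37_trace.dilation_factor == 1.0
        cold = simulate_current(scale_for_temperature(wt_model, 27.0), dilate(protocol, 2.0))
        assert cold.temperature == 27.0
        assert cold.dilation_factor == 2.0

    def test_outward_current_peaking_late_in_ap(self, wt37_trace, protocol):
        """The hERG surge during repolarization: outward, maximal in the final
        third of the AP (pre-hold 100 ms, AP 100-400 ms)."""
        peak_idx = int(np.argmax(wt37_trace.current))
        t_peak = wt37_trace.times[peak_idx]
        assert 300.0 < t_peak < 400.0
        assert wt37_trace.current[peak_idx] > 0
        # frozen regression value for the packaged model
        assert t_peak == pytest.approx(328.0, abs=2.0)
        assert repolarization_power(wt37_trace).value == pytest.approx(22.45, abs=0.25)

    def test_zero_conductance_zero_current(self, wt_model, coarse_protocol):
        silent = dataclasses.replace(wt_model, g_max=0.0)
        tr = simulate_current(silent, coarse_protocol)
        assert np.all(tr.current == 0.0)

    def test_tolerance_refinement_stable(self, wt_model, coarse_protocol):
        """Tenfold tighter solver tolerances move the integral < 0.01%."""
        m = scale_for_temperature(wt_model, 37.0)
        r1 = repolarization_power(simulate_current(m, coarse_protocol, 1e-8, 1e-10)).value
        r2 = repolarization_power(simulate_current(m, coarse_protocol, 1e-9, 1e-11)).value
        assert abs(r1 / r2 - 1) < 1e-4

    def test_time_rescaling_equivariance(self, wt_model, coarse_protocol):
        """Uniformly slowing all rates and the conductance by f while dilating
        the command by f reproduces the reference trace after correction."""
        f = 2.0
        m = wt_model
        slow = dataclasses.replace(
            m,
            activation=dataclasses.replace(
                m.activation,
                alpha=m.activation.alpha.scaled(1 / f),
                beta=m.activation.beta.scaled(1 / f),
            ),
            inactivation=dataclasses.replace(
                m.inactivation,
                alpha=m.inactivation.alpha.scaled(1 / f),
                beta=m.inactivation.beta.scaled(1 / f),
            ),
            g_max=m.g_max / f,
        )
        ref = simulate_current(m, coarse_protocol)
        cold = simulate_current(slow, dilate(coarse_protocol, f))
        corrected = correct_trace(cold, f)
        err = np.max(np.abs(corrected.current - ref.current)) / np.max(np.abs(ref.current))
        assert err < 1e-3
        np.testing.assert_allclose(corrected.times, ref.times, rtol=1e-12)


class TestArtifacts:
    def test_all_zero_params_identity(self, wt37_trace, protocol):
        out = add_artifacts(wt37_trace, ArtifactParams(), protocol)
        assert out is wt37_trace

    def test_seeded_reproducibility(self, wt37_trace, protocol):
        params = ArtifactParams(noise_sd=5.0, rng_seed=42)
        a = add_artifacts(wt37_trace, params, protocol)
        b = add_artifacts(wt37_trace, params, protocol)
        np.testing.assert_array_equal(a.current, b.current)

    def test_contamination_is_inward_late(self, wt37_trace, protocol):
        params = ArtifactParams(contamination_amplitude=30.0)
        out = add_artifacts(wt37_trace, params, protocol)
        late = out.times > 0.9 * out.times[-1]
        assert np.min(out.current[late]) < 0  # inward = negative
        early = out.times < 0.5 * out.times[-1]
        np.testing.assert_array_equal(out.current[early], wt37_trace.current[early])

    def test_leak_is_ohmic_in_command_voltage(self, wt37_trace, protocol):
        params = ArtifactParams(leak_conductance=0.5, leak_reversal=0.0)
        out = add_artifacts(wt37_trace, params, protocol)
        np.testing.assert_allclose(
            out.current - wt37_trace.current, 0.5 * protocol.voltages, rtol=1e-12
        )

    def test_mismatched_grid_rejected(self, wt_model, protocol, coarse_protocol):
        tr = simulate_current(wt_model, coarse_protocol)
        with pytest.raises(ValueError, match="grid"):
            add_artifacts(tr, ArtifactParams(noise_sd=1.0), protocol)


class TestPopulation:
    def test_degenerate_population_equals_single_cell(self, wt_model, coarse_protocol):
        single = simulate_current(wt_model, coarse_protocol)
        pop = simulate_population(wt_model, coarse_protocol, 1, 0.0, rng_seed=3)
        np.testing.assert_allclose(pop[0].current, single.current, rtol=1e-12)

    def test_same_seed_bitwise_identical(self, wt_model, coarse_protocol):
        kw = dict(n_cells=5, conductance_cv=0.3, artifacts=ArtifactParams(noise_sd=5.0))
        a = simulate_population(wt_model, coarse_protocol, rng_seed=11, **kw)
        b = simulate_population(wt_model, coarse_protocol, rng_seed=11, **kw)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.current, tb.current)

    def test_lognormal_is_mean_preserving(self, wt_model, coarse_protocol):
        """cv=0.3, n=50: mean repower within 10% of the deterministic value
        (the log-normal is parameterized to have mean g_max)."""
        pop = simulate_population(wt_model, coarse_protocol, 50, 0.3, rng_seed=0)
        mean_rp = np.mean([repolarization_power(t).value for t in pop])
        single_rp = repolarization_power(simulate_current(wt_model, coarse_protocol)).value
        assert abs(mean_rp / single_rp - 1) < 0.10
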