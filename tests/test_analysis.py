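import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergpower import (
    CurrentTrace,
    blank_late_artifact,
    correct_trace,
    normalize_to_peak,
    repolarization_power,
    scan_factors,
    time_of_peak,
    trace_discrepancy,
)


def trace_from(times, current, factor=1.0, temp=22.0):
    return CurrentTrace(
        times=np.asarray(times, float),
        current=np.asarray(current, float),
        temperature=temp,
        dilation_factor=factor,
    )


class TestRepolarizationPower:
    def test_rectangle(self):
        t = np.linspace(0, 500, 501)
        rp = repolarization_power(trace_from(t, np.full_like(t, 10.0)))
        assert rp.value == pytest.approx(5.0)  # 10 pA × 0.5 s

    def test_zero_trace(self):
        t = np.linspace(0, 100, 11)
        assert repolarization_power(trace_from(t, np.zeros_like(t))).value == 0.0

    def test_triangle(self):
        t = np.linspace(0, 400, 401)
        c = np.interp(t, [0, 200, 400], [0, 100, 0])
        assert repolarization_power(trace_from(t, c)).value == pytest.approx(20.0)

    def test_negative_excursions_integrate_with_sign(self):
        t = np.linspace(0, 1000, 1001)
        c = np.where(t < 500, 10.0, -10.0)
        assert repolarization_power(trace_from(t, c)).value == pytest.approx(0.0, abs=0.02)

    def test_subwindow_interpolates_bounds(self):
        t = np.linspace(0, 500, 501)
        rp = repolarization_power(trace_from(t, np.full_like(t, 10.0)), 100.5, 350.25)
        assert rp.value == pytest.approx(10.0 * (350.25 - 100.5) / 1000)
        assert (rp.window_start, rp.window_end) == (100.5, 350.25)

    def test_window_outside_span_rejected(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(ValueError, match="window"):
            repolarization_power(trace_from(t, np.zeros_like(t)), 0.0, 200.0)


class TestCorrectTrace:
    def test_identity(self):
        t = np.linspace(0, 100, 101)
        tr = trace_from(t, np.sin(t / 10))
        out = correct_trace(tr, 1.0)
        np.testing.assert_array_equal(out.times, tr.times)
        np.testing.assert_array_equal(out.current, tr.current)

    def test_undoes_dilation_metadata(self):
        t = np.linspace(0, 600, 301)
        tr = trace_from(t, np.ones_like(t), factor=2.0)
        out = correct_trace(tr, 2.0)
        assert out.dilation_factor == pytest.approx(1.0)
        assert out.times[-1] == pytest.approx(300.0)
        np.testing.assert_allclose(out.current, 2.0, rtol=1e-15)

    def test_mismatched_factor_warns(self):
        t = np.linspace(0, 100, 101)
        with pytest.warns(UserWarning, match="dilation"):
            correct_trace(trace_from(t, np.ones_like(t), factor=3.0), 2.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        factor=st.floats(0.5, 5.0, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_correction_preserves_time_integral(self, factor, seed):
        """t = f·s substitution: ×f on current and ÷f on time cancel exactly."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        t = np.sort(rng.uniform(0.1, 1000.0, size=n))
        t = np.concatenate(([0.0], t))
        c = rng.normal(0.0, 50.0, size=len(t))
        tr = trace_from(t, c, factor=factor)
        raw = repolarization_power(tr).value
        corrected = repolarization_power(correct_trace(tr, factor)).value
        assert corrected == pytest.approx(raw, rel=1e-10, abs=1e-12)


class TestTimeOfPeak:
    def test_triangle_peak(self):
        t = np.linspace(0, 400, 401)
        c = np.interp(t, [0, 200, 400], [0, 100, 0])
        assert time_of_peak(trace_from(t, c)) == 200.0

    def test_tie_broken_earliest(self):
        t = np.linspace(0, 4, 5)
        assert time_of_peak(trace_from(t, [0, 5, 5, 5, 0])) == 1.0

    def test_flat_trace_warns_and_returns_start(self):
        t = np.linspace(0, 10, 11)
        with pytest.warns(UserWarning, match="degenerate"):
            assert time_of_peak(trace_from(t, np.ones_like(t))) == 0.0


class TestNormalizeToPeak:
    def test_unit_maximum_and_idempotence(self, wt37_trace):
        n1 = normalize_to_peak(wt37_trace)
        assert np.max(n1.current) == pytest.approx(1.0)
        n2 = normalize_to_peak(n1)
        np.testing.assert_allclose(n2.current, n1.current, rtol=1e-15)

    def test_scale_invariance(self):
        t = np.linspace(0, 100, 101)
        c = np.interp(t, [0, 60, 100], [0, 30, 5])
        a = normalize_to_peak(trace_from(t, c))
        b = normalize_to_peak(trace_from(t, 7.3 * c))
        np.testing.assert_allclose(a.current, b.current, rtol=1e-12)

    def test_nonpositive_peak_rejected(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="maximum"):
            normalize_to_peak(trace_from(t, -np.ones_like(t)))


class TestTraceDiscrepancy:
    def test_identical_traces_zero(self, wt37_trace):
        assert trace_discrepancy(wt37_trace, wt37_trace) == 0.0

    def test_constant_offset_gives_offset_rms(self):
        t = np.linspace(0, 100, 201)
        c = np.sin(t / 5)
        a = trace_from(t, c)
        b = trace_from(t, c + 7.0)
        assert trace_discrepancy(a, b) == pytest.approx(7.0)

    def test_disjoint_spans_rejected(self):
        a = trace_from([0.0, 1.0, 2.0], [0, 1, 0])
        b = CurrentTrace(
            times=np.array([3.0, 4.0]),
            current=np.array([0.0, 1.0]),
            temperature=22.0,
            dilation_factor=1.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            trace_discrepancy(a, b)


class TestBlankLateArtifact:
    def test_zeroes_only_late_negative_samples(self):
        t = np.linspace(0, 100, 101)
        c = np.where(t > 80, -5.0, 10.0)
        out = blank_late_artifact(trace_from(t, c), terminal_fraction=0.3)
        assert np.all(out.current[t > 80] == 0.0)
        assert np.all(out.current[t <= 70] == 10.0)


class TestScanFactors:
    def test_no_temperature_gap_selects_unity(self, wt_model, coarse_protocol):
        res = scan_factors(wt_model, coarse_protocol, 37.0, 37.0, [1.0, 2.0])
        assert res.best_factor == 1.0
        assert res.discrepancy_by_factor[1.0] == 0.0
        assert res.discrepancy_by_factor[2.0] > 0.0

    def test_density_normalization_does_not_change_selection(self, wt_model, coarse_protocol):
        fs = [1.0, 1.5, 2.0]
        raw = scan_factors(wt_model, coarse_protocol, 37.0, 27.0, fs)
        dens = scan_factors(wt_model, coarse_protocol, 37.0, 27.0, fs, capacitance_pF=20.0)
        assert raw.best_factor == dens.best_factor
        for f in fs:
            assert dens.repower_by_factor[f] == pytest.approx(
                raw.repower_by_factor[f] / 20.0, rel=1e-12
            )

    def test_nonpositive_factor_rejected(self, wt_model, coarse_protocol):
        with pytest.raises(ValueError, match="factor"):
            scan_factors(wt_model, coarse_protocol, 37.0, 27.0, [0.0, 1.0])
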