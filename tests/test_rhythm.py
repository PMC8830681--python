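"""Oscillator fitting, rhythm classification gates, multiple-testing
adjustments and time-base conversions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from circaquant.rhythm import (
    EchoRhythmFitter,
    EhoFit,
    RhythmCriteria,
    adjust_pvalues,
    carrier_zenith,
    circular_separation,
    classify_rhythm,
    fit_catalog,
    fit_eho,
    preprocess_series,
    rhythm_pvalue,
    time_convert,
    zenith_nadir,
)
from circaquant.synth import GroundTruthRhythm, phase_for_zenith, rhythm_value


def _series(t, values, replicate=1):
    return pd.DataFrame({"time_ps": t, "replicate": replicate, "value": values})


class TestPreprocessSeries:
    def test_pure_line_removed(self):
        t = np.arange(0, 30, 2.0)
        pre, (slope, intercept) = preprocess_series(_series(t, 2 * t + 1),
                                                    smooth=False)
        assert np.allclose(pre["value"], 0.0, atol=1e-10)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_constant_series_zeroed(self):
        t = np.arange(0, 20, 4.0)
        pre, _ = preprocess_series(_series(t, np.full_like(t, 7.0)), smooth=False)
        assert np.allclose(pre["value"], 0.0, atol=1e-12)

    def test_smoothing_matches_convolution_oracle(self):
        t = np.arange(0, 48.1, 4.0)
        y = np.cos(2 * np.pi * t / 24) + 0.5 * t
        pre, (slope, b) = preprocess_series(_series(t, y), smooth=True)
        detrended = y - (slope * t + b)
        expected = np.empty_like(detrended)
        for i in range(len(detrended)):  # brute-force (1,2,1)/4 with edge renorm
            idx = [j for j in (i - 1, i, i + 1) if 0 <= j < len(detrended)]
            w = [2.0 if j == i else 1.0 for j in idx]
            expected[i] = np.dot(w, detrended[idx]) / sum(w)
        assert np.allclose(pre.sort_values("time_ps")["value"], expected)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            preprocess_series(_series([0.0, 4.0], [1.0, 2.0]))


class TestFitEho:
    def test_noiseless_recovery(self):
        truth = GroundTruthRhythm(2.0, 0.05, 24.0, 0.0, 10.0)
        t = np.arange(0, 48.1, 2.0)
        fit = fit_eho(t, rhythm_value(truth, t, 0.0), t0=0.0)
        assert fit.period == pytest.approx(24.0, abs=0.1)
        assert fit.ac_coeff == pytest.approx(0.05, abs=0.005)
        assert fit.amplitude == pytest.approx(2.0, rel=0.01)
        assert fit.phase == pytest.approx(0.0, abs=0.01) or \
            fit.phase == pytest.approx(2 * math.pi, abs=0.01)

    def test_constant_series_flat_fit(self):
        t = np.arange(0, 48.1, 4.0)
        fit = classify_rhythm(fit_eho(t, np.full_like(t, 3.0)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert not fit.circadian

    def test_ultradian_signal_not_circadian(self):
        t = np.arange(0, 48.1, 2.0)
        y = np.cos(2 * np.pi * t / 12.0)
        fit = classify_rhythm(fit_eho(t, y))
        assert not fit.circadian

    def test_sse_never_above_constant_model(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = np.sort(rng.uniform(0, 48, 12))
            y = rng.normal(0, 1, 12)
            fit = fit_eho(t, y)
            assert fit.sse <= fit.sse_constant + 1e-9


class TestRhythmPvalue:
    def test_kendall_perfect_agreement_exact_tail(self):
        y = np.arange(8.0)
        p = rhythm_pvalue(y, y, method="kendall")
        assert p == pytest.approx(1.0 / math.factorial(8), rel=1e-9)

    def test_constant_fit_uninformative(self):
        assert rhythm_pvalue(np.ones(10), np.arange(10.0), method="kendall") == 1.0

    def test_anticorrelated_fit_not_significant(self):
        y = np.arange(10.0)
        assert rhythm_pvalue(-y, y, method="kendall") >= 0.5

    def test_too_few_points(self):
        assert rhythm_pvalue([1, 2, 3], [1, 2, 3]) == 1.0

    def test_ftest_perfect_fit_tiny_noise(self):
        t = np.arange(0, 48.1, 2.0)
        truth = GroundTruthRhythm(2.0, 0.0, 24.0, 0.0, 0.0)
        rng = np.random.default_rng(1)
        y = rhythm_value(truth, t, 0.0) + rng.normal(0, 0.01, len(t))
        fit = fit_eho(t, y)
        assert fit.p < 1e-10


class TestAdjustPvalues:
    def _bh_oracle(self, p):
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_reference_examples(self):
        p = [0.01, 0.02, 0.03, 0.04]
        bh, by = adjust_pvalues(p)
        assert np.allclose(bh, 0.04)
        assert np.allclose(by, 0.04 * 25 / 12)

    def test_single_pvalue_identity(self):
        bh, by = adjust_pvalues([0.03])
        assert bh[0] == pytest.approx(0.03)
        assert by[0] == pytest.approx(0.03)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_stepup_oracle_and_invariants(self, p):
        p = np.asarray(p)
        bh, by = adjust_pvalues(p)
        cm = sum(1.0 / k for k in range(1, len(p) + 1))
        assert np.allclose(bh, self._bh_oracle(p), atol=1e-12)
        assert np.allclose(by, np.minimum(self._bh_oracle(p) * cm, 1.0), atol=1e-12)
        assert np.all(bh <= by + 1e-12)
        assert np.all(bh >= p - 1e-12) and np.all(by <= 1 + 1e-12)
        # order preservation
        order = np.argsort(p)
        assert np.all(np.diff(bh[order]) >= -1e-12)


class TestClassify:
    def _fit(self, period, ac, p):
        return EhoFit(amplitude=1.0, ac_coeff=ac, period=period, phase=0.0,
                      equilibrium=0.0, t0=0.0, sse=1.0, sse_constant=2.0,
                      p=p, p_bh=p, p_by=p)

    def test_circadian_passes_all_gates(self):
        fit = classify_rhythm(self._fit(26.0, 0.05, 1.61e-6))
        assert fit.circadian and fit.reasons == []

    @pytest.mark.parametrize("period,ac,p,expected_reason", [
        (26.0, 0.30, 1e-9, "ac_coefficient"),
        (17.9, 0.0, 1e-9, "period"),
        (30.1, 0.0, 1e-9, "period"),
        (26.0, 0.0, 0.2, "p_value"),
    ])
    def test_failed_gate_named(self, period, ac, p, expected_reason):
        fit = classify_rhythm(self._fit(period, ac, p))
        assert not fit.circadian
        assert expected_reason in fit.reasons


class TestZenithNadir:
    def test_undamped_cosine_extrema(self):
        fit = EhoFit(amplitude=1.0, ac_coeff=0.0, period=24.0, phase=0.0,
                     equilibrium=0.0, t0=16.0, sse=0, sse_constant=1, p=0.01)
        zen, nad, clipped = zenith_nadir(fit, (16.0, 40.0))
        assert zen == pytest.approx(16.0, abs=0.02)
        assert nad == pytest.approx(28.0, abs=0.02)

    def test_damped_fit_matches_dense_grid(self):
        fit = EhoFit(amplitude=2.0, ac_coeff=0.04, period=24.0, phase=1.0,
                     equilibrium=5.0, t0=0.0, sse=0, sse_constant=1, p=0.01)
        zen, nad, _ = zenith_nadir(fit, (0.0, 48.0))
        tt = np.arange(0.0, 48.0001, 0.001)
        yy = fit.predict(tt)
        assert zen == pytest.approx(tt[np.argmax(yy)], abs=0.01)
        assert nad == pytest.approx(tt[np.argmin(yy)], abs=0.01)

    def test_window_excluding_peak_clips_and_flags(self):
        fit = EhoFit(amplitude=1.0, ac_coeff=0.0, period=24.0, phase=0.0,
                     equilibrium=0.0, t0=0.0, sse=0, sse_constant=1, p=0.01)
        zen, _, clipped = zenith_nadir(fit, (4.0, 20.0))
        assert clipped

    def test_zero_amplitude_undefined(self):
        fit = EhoFit(amplitude=0.0, ac_coeff=0.0, period=24.0, phase=0.0,
                     equilibrium=0.0, t0=0.0, sse=0, sse_constant=0, p=1.0)
        with pytest.raises(ValueError):
            zenith_nadir(fit, (0.0, 24.0))

    def test_carrier_zenith_matches_argmax_for_sustained_fit(self):
        fit = EhoFit(amplitude=1.0, ac_coeff=0.0, period=24.0,
                     phase=phase_for_zenith(32.0, 16.0, 24.0),
                     equilibrium=0.0, t0=16.0, sse=0, sse_constant=1, p=0.01)
        assert carrier_zenith(fit) == pytest.approx(32.0, abs=1e-6)

    def test_circular_separation_folds(self):
        assert circular_separation(31.0, 43.0, 24.0) == pytest.approx(12.0)
        assert circular_separation(2.0, 46.0, 24.0) == pytest.approx(4.0)


class TestTimeConvert:
    @pytest.mark.parametrize("value,frm,to,expected", [
        (0.0, "index", "PS", 16.0),
        (32.0, "PS", "CT", 20.0),
        (20.0, "PS", "CT", 8.0),
        (8.0, "CT", "PS", 20.0),
    ])
    def test_printed_pairings(self, value, frm, to, expected):
        assert time_convert(value, frm, to) == expected

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-100, 100), st.sampled_from(["index", "PS", "CT"]),
           st.sampled_from(["index", "PS", "CT"]))
    def test_round_trip_identity(self, x, a, b):
        assert time_convert(time_convert(x, a, b), b, a) == pytest.approx(x)

    def test_unknown_base_rejected(self):
        with pytest.raises(ValueError):
            time_convert(0.0, "PS", "ZT")


class TestEstimatorApi:
    def test_sklearn_protocol(self):
        est = EchoRhythmFitter(smooth=False, detrend=False)
        cloned = clone(est)
        assert cloned.get_params()["smooth"] is False
        truth = GroundTruthRhythm(2.0, 0.0, 24.0, 0.0, 10.0)
        t = np.arange(0, 48.1, 2.0)
        est.fit(t, rhythm_value(truth, t, 0.0))
        assert est.period_ == pytest.approx(24.0, abs=0.1)
        assert np.allclose(est.predict(t), rhythm_value(truth, t, 0.0), atol=1e-5)

    def test_fit_series_replicate_paths(self, noisy_catalog):
        series = noisy_catalog["series_0"]
        collapsed = EchoRhythmFitter(collapse_replicates=True).fit_series(series)
        resolved = EchoRhythmFitter(collapse_replicates=False).fit_series(series)
        for est in (collapsed, resolved):
            assert 18 <= est.period_ <= 30
            assert est.fit_.p < 0.05

    def test_catalog_gating_columns(self, noisy_catalog):
        sub = {k: noisy_catalog[k] for k in list(noisy_catalog)[:5]}
        fits = fit_catalog(sub, collapse_replicates=True)
        assert set(["p", "p_bh", "p_by", "circadian", "zenith_ps"]) <= set(fits.columns)
        assert (fits["p_bh"] >= fits["p"] - 1e-15).all()
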