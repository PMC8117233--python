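import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gazeperim.errors import ConfigError, ContaminationError, MalformedRecordError
from gazeperim.scotoma import ScotomaKind
from gazeperim.tfce import (
    BinarySeries,
    DeviationSeries,
    NormativeDistribution,
    TfceParams,
    TfceSeries,
    binarize,
    build_normative_distribution,
    deviation_series,
    tfce_transform,
)
from .conftest import make_record


def brute_force_tfce(values: np.ndarray, dt: float, params: TfceParams) -> np.ndarray:
    """Independent oracle: per height level, label contiguous supra-threshold
    runs with a scalar scan and accumulate per-sample terms."""
    v = np.asarray(values, dtype=float)
    h0, hmax = v.min(), v.max()
    out = np.zeros_like(v)
    if hmax == h0:
        return out
    dh = (hmax - h0) / params.n_steps
    unit = dt if params.extent_unit == "seconds" else 1.0
    for k in range(1, params.n_steps + 1):
        h = h0 + k * dh
        i = 0
        while i < len(v):
            if v[i] >= h:
                j = i
                while j < len(v) and v[j] >= h:
                    j += 1
                extent = (j - i) * unit
                term = extent ** params.E * h ** params.H * dh
                for t in range(i, j):
                    out[t] += term
                i = j
            else:
                i += 1
    return out


def _series(values, dt=1.0 / 240.0, **prov):
    return DeviationSeries(values=np.asarray(values, float), dt=dt, provenance=prov)


class TestDeviationSeries:
    def test_zero_when_gaze_equals_stimulus(self):
        n = 50
        rec = make_record(np.arange(n, dtype=float), np.ones(n),
                          np.arange(n, dtype=float), np.ones(n))
        assert np.all(deviation_series(rec).values == 0)

    def test_three_four_five(self):
        rec = make_record([0.0], [0.0], [3.0], [4.0])
        assert deviation_series(rec).values[0] == pytest.approx(5.0)

    def test_matches_per_sample_recomputation(self):
        rng = np.random.default_rng(8)
        n = 200
        rec = make_record(rng.normal(size=n), rng.normal(size=n),
                          rng.normal(size=n), rng.normal(size=n))
        d = deviation_series(rec).values
        for i in range(n):
            expected = np.sqrt((rec.p_x[i] - rec.s_x[i]) ** 2
                               + (rec.p_y[i] - rec.s_y[i]) ** 2)
            assert d[i] == pytest.approx(expected)


class TestTfceTransform:
    def test_constant_series_all_zero(self):
        for c in (0.0, 3.7):
            out = tfce_transform(_series(np.full(100, c)))
            assert np.all(out.values == 0)

    def test_rectangular_pulse_closed_form(self):
        # baseline-0 pulse of height h_p and duration d seconds:
        # limit value = d^2 * (2/3) * h_p^(3/2) at every in-pulse sample
        rate = 240.0
        h_p, d_sec = 3.0, 0.5
        n_pulse = int(d_sec * rate)
        v = np.zeros(1000)
        v[200:200 + n_pulse] = h_p
        out = tfce_transform(_series(v, dt=1.0 / rate),
                             TfceParams(E=2, H=0.5, n_steps=2500))
        expected = d_sec ** 2 * (2.0 / 3.0) * h_p ** 1.5
        inside = out.values[200:200 + n_pulse]
        assert np.allclose(inside, expected, rtol=0.01)
        assert np.all(out.values[:200] == 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        params = TfceParams(n_steps=50)
        for trial in range(20):
            v = rng.uniform(0, 5, size=200)
            dt = 1.0 / 240.0
            fast = tfce_transform(_series(v, dt=dt), params).values
            slow = brute_force_tfce(v, dt, params)
            np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_extent_in_samples_supported(self):
        v = np.random.default_rng(2).uniform(0, 5, 100)
        params = TfceParams(n_steps=40, extent_unit="samples")
        fast = tfce_transform(_series(v), params).values
        slow = brute_force_tfce(v, 1.0 / 240.0, params)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(MalformedRecordError):
            tfce_transform(_series([]))

    def test_negative_values_rejected(self):
        with pytest.raises(MalformedRecordError):
            tfce_transform(_series([1.0, -0.5]))

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 3, size=150)
        params = TfceParams(n_steps=60)
        a = tfce_transform(_series(v), params).values
        b = tfce_transform(_series(v[::-1]), params).values
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_scaling_property(self):
        # with h0 = 0, scaling D by c scales TFCE by c^(H+1)
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 2, size=100)
        v[0] = 0.0
        params = TfceParams(n_steps=80)
        c = 3.0
        a = tfce_transform(_series(v), params).values
        b = tfce_transform(_series(c * v), params).values
        np.testing.assert_allclose(b, c ** (params.H + 1) * a, rtol=1e-9)

    @given(hnp.arrays(np.float64, st.integers(10, 60),
                      elements=st.floats(0, 5, allow_nan=False)),
           st.data())
    @settings(max_examples=40, deadline=None)
    def test_pointwise_monotone_fixed_height_grid(self, v, data):
        # raising a sample never decreases any TFCE value, provided min and
        # max (hence the height grid) are unchanged; perturbing the unique
        # minimum shrinks the integration range from below (h0 = min D), so
        # unconstrained pointwise monotonicity does not hold
        if np.ptp(v) == 0:
            return
        params = TfceParams(n_steps=30)
        base = tfce_transform(_series(v), params).values
        i = data.draw(st.integers(0, len(v) - 1))
        assume(v[i] > v.min() or np.sum(v == v.min()) > 1)
        v2 = v.copy()
        v2[i] = data.draw(st.floats(float(v[i]), float(v.max())))
        bumped = tfce_transform(_series(v2), params).values
        assert np.all(bumped >= base - 1e-12)

    def test_pointwise_monotone_raising_max(self):
        # raising the max rescales dh; monotone up to discretization error
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 4, size=120)
        params = TfceParams(n_steps=2500)
        base = tfce_transform(_series(v), params).values
        v2 = v.copy()
        v2[np.argmax(v)] *= 1.3
        bumped = tfce_transform(_series(v2), params).values
        tol = 1e-3 * max(base.max(), 1.0)
        assert np.all(bumped >= base - tol)


class TestNormativeDistribution:
    def test_pooling_counts(self):
        s1 = TfceSeries(np.arange(10.0), TfceParams(), 0, 9, 1 / 240,
                        {"condition": "none", "participant_id": "P01"})
        s2 = TfceSeries(np.arange(10.0), TfceParams(), 0, 9, 1 / 240,
                        {"condition": "none", "participant_id": "P02"})
        F = build_normative_distribution([s1, s2])
        assert F.values.size == 20
        assert F.source_ids == ["P01", "P02"]

    def test_single_trial_distribution(self):
        vals = np.array([0.0, 1.0, 2.0])
        s = TfceSeries(vals, TfceParams(), 0, 2, 1 / 240, {"condition": "none"})
        F = build_normative_distribution([s])
        np.testing.assert_array_equal(F.values, vals)

    def test_contamination_rejected(self):
        s = TfceSeries(np.arange(5.0), TfceParams(), 0, 4, 1 / 240,
                       {"condition": ScotomaKind.CENTRAL.value, "trial_id": "T1"})
        with pytest.raises(ContaminationError):
            build_normative_distribution([s])

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            build_normative_distribution([])

    def test_percentile_matches_sorting_oracle(self):
        rng = np.random.default_rng(9)
        mix = np.concatenate([rng.normal(1, 0.1, 50) ** 2,
                              rng.normal(3, 0.5, 150) ** 2])
        F = NormativeDistribution(values=mix)
        assert F.percentile(90) == pytest.approx(np.percentile(np.sort(mix), 90))
        assert F.percentile(100) == pytest.approx(mix.max())


class TestBinarize:
    def _F(self):
        return NormativeDistribution(values=np.arange(1.0, 101.0))

    def test_lambda_100_flags_only_above_max(self):
        F = self._F()
        out = binarize(np.array([50.0, 100.0, 100.1]), F, 100)
        np.testing.assert_array_equal(out.flags, [0, 0, 1])

    def test_values_at_threshold_not_flagged(self):
        F = self._F()
        thr = F.percentile(90)
        out = binarize(np.full(5, thr), F, 90)
        assert np.all(out.flags == 0)

    def test_percentile_90_example(self):
        out = binarize(np.array([50.0, 95.0]), self._F(), 90)
        np.testing.assert_array_equal(out.flags, [0, 1])
        assert out.threshold_value == pytest.approx(np.percentile(np.arange(1.0, 101.0), 90))

    def test_lambda_out_of_range(self):
        with pytest.raises(ConfigError):
            binarize(np.array([1.0]), self._F(), 0.5)

    @given(lam1=st.integers(1, 100), lam2=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_flagged_fraction_monotone_in_lambda(self, lam1, lam2):
        rng = np.random.default_rng(11)
        F = NormativeDistribution(values=rng.exponential(1.0, 500))
        series = rng.exponential(1.5, 300)
        lo, hi = sorted((lam1, lam2))
        f_lo = binarize(series, F, lo).flags.mean()
        f_hi = binarize(series, F, hi).flags.mean()
        assert f_hi <= f_lo + 1e-12
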