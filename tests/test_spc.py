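"""EWMA statistic, percentile limits, monitoring and block-size search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbrtqc import datagen, spc


def ewma_bruteforce(series, lam, init):
    """Independent oracle: the literal recursion, one step at a time."""
    out = []
    prev = init
    for x in series:
        prev = (1.0 - lam) * prev + lam * x
        out.append(prev)
    return np.array(out)


class TestEWMA:
    def test_single_step(self):
        assert spc.ewma([16.0], lam=1 / 3, init=10.0) == pytest.approx([12.0])

    def test_constant_series_is_fixed_point(self):
        out = spc.ewma(np.full(100, 7.5), lam=0.2, init=7.5)
        assert np.allclose(out, 7.5)

    def test_unit_weight_returns_input(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert np.array_equal(spc.ewma(x, lam=1.0, init=99.0), x)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=200),
        st.floats(0.01, 1.0),
        st.floats(-50, 50),
    )
    def test_matches_bruteforce_recursion(self, xs, lam, init):
        out = spc.ewma(xs, lam, init)
        assert np.allclose(out, ewma_bruteforce(xs, lam, init), atol=1e-12, rtol=0)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=100),
        st.floats(0.01, 1.0),
        st.floats(-50, 50),
    )
    def test_bounded_by_init_and_series(self, xs, lam, init):
        out = spc.ewma(xs, lam, init)
        lo = min(min(xs), init)
        hi = max(max(xs), init)
        assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            spc.ewma([], lam=0.5, init=0.0)

    def test_block_size_to_weight(self):
        assert spc.lambda_for_block(220) == pytest.approx(2 / 221)
        with pytest.raises(ValueError):
            spc.lambda_for_block(0)


class TestPercentileLimits:
    def test_interpolated_order_statistics(self):
        # type-7 quantiles of 1..10000 at 0.05% / 99.95%
        lo, hi = spc.percentile_limits(np.arange(1.0, 10001.0))
        assert lo == pytest.approx(5.9995)
        assert hi == pytest.approx(9995.0005)

    def test_constant_series_degenerates(self):
        lo, hi = spc.percentile_limits(np.full(5000, 3.3))
        assert lo == hi == 3.3

    def test_short_input_warns(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            spc.percentile_limits(np.arange(100.0))

    def test_exceedance_near_design_rate(self, rng):
        """On the limit-setting series itself the strict exceedance is ~0.1%."""
        stat = spc.ewma(rng.normal(size=100_000), lam=0.1, init=0.0)
        lo, hi = spc.percentile_limits(stat)
        frac = float(((stat < lo) | (stat > hi)).mean())
        # binomial 99% CI around 0.001 at n=100k: (0.00074, 0.00126)
        assert 0.00074 < frac < 0.00126


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(777)
    train = rng.normal(size=100_000)
    lam = spc.lambda_for_block(40)
    init = float(train.mean())
    stat = spc.ewma(train, lam, init)
    lo, hi = spc.percentile_limits(stat)
    params = spc.EWMAParams(block_size=40, lam=lam, lower=lo, upper=hi, init=init)
    return train, params


class TestRunMonitor:
    def test_error_free_alarm_rate_calibrated(self, fitted, rng):
        train, params = fitted
        alarms = []
        for _ in range(5):
            cs = spc.run_monitor(rng.normal(size=10_000), params, train)
            alarms.append(cs.alarms)
        frac = float(np.concatenate(alarms).mean())
        # near the 0.1% design rate; the band covers the sampling noise
        # of the extreme-quantile limit estimate itself
        assert 0.0002 < frac < 0.004

    def test_gross_shift_detected_within_block(self, fitted, rng):
        train, params = fitted
        window = rng.normal(size=2000)
        window[1000:] += 10.0  # +10 SD step
        cs = spc.run_monitor(window, params, train)
        post = np.flatnonzero(cs.alarms[1000:])
        assert post.size > 0 and post[0] < params.block_size

    def test_wider_limits_never_add_alarms(self, fitted, rng):
        train, params = fitted
        window = rng.normal(size=5000)
        window[2000:] += 2.0
        base = spc.run_monitor(window, params, train)
        import dataclasses

        wide = dataclasses.replace(params, limit_scale=1.25)
        scaled = spc.run_monitor(window, wide, train)
        assert np.all(scaled.alarms <= base.alarms)

    def test_alarm_flag_definition(self, fitted, rng):
        train, params = fitted
        cs = spc.run_monitor(rng.normal(size=3000), params, train)
        expect = (cs.statistic < cs.lower) | (cs.statistic > cs.upper)
        assert np.array_equal(cs.alarms, expect)


def _gaussian_stream(values, spec):
    import pandas as pd

    n = len(values)
    frame = pd.DataFrame(
        {
            "barcode": [f"G{i:07d}" for i in range(n)],
            "order_index": np.arange(n),
            "analyte": spec.name,
            "value": values,
            "age": 60,
            "sex": "F",
            "patient_category": "outpatient",
            "department": "general",
            "diagnosis": "D00",
        }
    )
    return datagen.AnalyteStream(spec=spec, frame=frame)


class TestGridSearch:
    def test_tie_breaks_to_smallest_block(self, rng, cea_spec):
        # a generous DFAR admits every candidate and an empty bias menu
        # scores them identically: the tie must go to the smallest N
        train = _gaussian_stream(rng.normal(10, 1, 30000), cea_spec)
        val = _gaussian_stream(rng.normal(10, 1, 10000), cea_spec)
        res = spc.grid_search(
            train, val, candidate_N=(70, 10, 220), dfar=0.05, bias_menu=(),
            window=2000, margin=400,
        )
        assert res.status == "ok"
        assert res.params.block_size == 10

    def test_single_admissible_candidate_selected(self, cea_splits):
        tr, va, _ = cea_splits
        res = spc.grid_search(
            tr, va, candidate_N=(100,), reps=2, window=2000, margin=400, seed=1
        )
        assert res.params.block_size == 100
        assert res.status != "uncontrolled" or res.far_validation > 0.001

    def test_variance_inflation_triggers_escalation(self, rng, cea_spec):
        """Validation noisier than training: scale 1.0 fails, 1.25 controls."""
        train = _gaussian_stream(rng.normal(10, 1.0, 40000), cea_spec)
        val = _gaussian_stream(rng.normal(10, 1.12, 20000), cea_spec)
        res = spc.grid_search(
            train, val, candidate_N=(40, 100), bias_menu=(), window=3000, margin=500
        )
        assert res.status == "escalated"
        assert res.far_validation <= 0.001
        assert res.params.limit_scale == 1.25

    def test_hopeless_far_reported_uncontrolled(self, rng, cea_spec):
        train = _gaussian_stream(rng.normal(10, 1.0, 40000), cea_spec)
        val = _gaussian_stream(rng.normal(10, 2.0, 20000), cea_spec)
        res = spc.grid_search(
            train, val, candidate_N=(40,), bias_menu=(), window=3000, margin=500
        )
        assert res.status == "uncontrolled"
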