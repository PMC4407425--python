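"""Baselines, desaturation-event detection, and the four ODI variants."""

import numpy as np
import pytest

from conftest import make_trace
from odisleep.odi import (
    ODIParams,
    baseline_all_night,
    baseline_series,
    baseline_top20_preceding,
    compute_odi,
    detect_events,
)


def brute_force_events(trace, params):
    """Independent oracle: test every sample against its baseline and group
    runs by direct iteration."""
    if params.baseline_mode == "A":
        valid_vals = trace.spo2[trace.valid]
        base = [valid_vals.mean()] * len(trace) if valid_vals.size else [None] * len(trace)
    else:
        base = [
            baseline_top20_preceding(trace, t, min_window_samples=params.min_window_samples)
            for t in range(len(trace))
        ]
    qualifies = [
        trace.valid[t]
        and base[t] is not None
        and not np.isnan(base[t])
        and trace.spo2[t] <= base[t] - params.threshold_n
        for t in range(len(trace))
    ]
    min_len = params.min_duration_s + (1 if params.strict_gt else 0)
    events, t = [], 0
    while t < len(trace):
        if qualifies[t]:
            start = t
            while t < len(trace) and qualifies[t]:
                t += 1
            if t - start >= min_len:
                events.append((start, t - 1))
        else:
            t += 1
    return events


class TestBaselines:
    def test_all_night_mean_over_valid_samples(self):
        tr = make_trace([90, 100, 90, 100])
        assert np.allclose(baseline_all_night(tr), 95.0)

    def test_all_night_excludes_invalid_samples(self):
        tr = make_trace([96, 96, 40, 96], valid=np.array([True, True, False, True]))
        assert np.allclose(baseline_all_night(tr), 96.0)

    def test_all_night_undefined_without_valid_samples(self):
        tr = make_trace([96, 96], valid=np.zeros(2, dtype=bool))
        with pytest.raises(ValueError):
            baseline_all_night(tr)

    def test_top20_of_constant_window(self):
        tr = make_trace(np.full(100, 95.0))
        assert baseline_top20_preceding(tr, 80) == pytest.approx(95.0)

    def test_top20_selects_largest_fifth(self):
        # preceding minute: 48 samples at 90 then 12 at 95; the top
        # ceil(0.2*60)=12 values are exactly the 95s
        values = np.concatenate([[90.0] * 48, [95.0] * 12, [80.0]])
        tr = make_trace(values)
        assert baseline_top20_preceding(tr, 60) == pytest.approx(95.0)

    def test_top20_undefined_below_min_window(self):
        tr = make_trace(np.full(100, 95.0))
        assert baseline_top20_preceding(tr, 5) is None

    def test_series_matches_scalar_on_masked_trace(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(85, 99, 300)
        valid = rng.random(300) > 0.2
        tr = make_trace(values, valid=valid)
        series = baseline_series(tr, "T")
        for t in [0, 11, 60, 150, 299]:
            scalar = baseline_top20_preceding(tr, t)
            if scalar is None:
                assert np.isnan(series[t])
            else:
                assert series[t] == pytest.approx(scalar, abs=1e-9)


class TestDetectEvents:
    def test_simple_dip_detected_with_duration_and_nadir(self):
        values = np.full(200, 95.0)
        values[100:105] = 90.0
        events = detect_events(make_trace(values), ODIParams(4.0, "A"))
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_s, ev.end_s, ev.duration_s) == (100, 104, 5)
        assert ev.nadir_pct == 90.0

    def test_two_sample_dip_too_short(self):
        values = np.full(200, 95.0)
        values[100:102] = 88.0
        assert detect_events(make_trace(values), ODIParams(4.0, "A")) == []

    def test_shallow_dip_below_threshold_ignored(self):
        values = np.full(200, 95.0)
        values[100:103] = 92.0  # 3-point drop < 4-point threshold
        assert detect_events(make_trace(values), ODIParams(4.0, "A")) == []

    def test_strict_gt_requires_four_samples(self):
        values = np.full(200, 96.0)
        values[100:103] = 80.0
        lenient = detect_events(make_trace(values), ODIParams(4.0, "A"))
        strict = detect_events(
            make_trace(values), ODIParams(4.0, "A", strict_gt=True)
        )
        assert len(lenient) == 1 and strict == []

    def test_invalid_sample_breaks_run(self):
        values = np.full(200, 96.0)
        values[100:110] = 80.0
        valid = np.ones(200, dtype=bool)
        valid[104] = False
        events = detect_events(make_trace(values, valid=valid), ODIParams(4.0, "A"))
        assert [(e.start_s, e.end_s) for e in events] == [(100, 103), (105, 109)]

    @pytest.mark.parametrize("mode", ["A", "T"])
    @pytest.mark.parametrize("n", [2.0, 3.0, 4.0])
    def test_matches_brute_force_oracle(self, mode, n):
        rng = np.random.default_rng(42)
        for _ in range(15):
            length = int(rng.integers(60, 601))
            values = 96 - np.abs(rng.normal(0, 3, length)).cumsum() % 12
            valid = rng.random(length) > 0.05
            tr = make_trace(values, valid=valid)
            params = ODIParams(n, mode)
            got = [(e.start_s, e.end_s) for e in detect_events(tr, params)]
            assert got == brute_force_events(tr, params)


class TestComputeOdi:
    def test_square_wave_events_counted_exactly(self):
        """30 planted square dips of depth 6 below a flat 96 trace over six
        valid hours give ODI4A = 30/6 = 5."""
        values = np.full(21600, 96.0)
        for k in range(30):
            start = 300 + k * 700
            values[start : start + 20] = 90.0
        result = compute_odi(make_trace(values))
        assert result.odi4a == pytest.approx(5.0)
        assert result.valid_hours == pytest.approx(6.0)

    def test_flat_trace_gives_zero_everywhere(self, flat_trace):
        result = compute_odi(flat_trace)
        assert (result.odi2, result.odi3, result.odi4t, result.odi4a) == (0, 0, 0, 0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            values = 96 - np.abs(rng.normal(0, 2.5, 2000)).cumsum() % 10
            result = compute_odi(make_trace(values))
            assert result.odi4t <= result.odi3 <= result.odi2

    def test_rate_invariant_under_trace_duplication(self):
        # a quiet first minute keeps the moving-baseline warm-up region
        # event-free, so doubling the trace doubles both events and hours
        rng = np.random.default_rng(3)
        values = np.concatenate(
            [np.full(60, 96.0), 96 - np.abs(rng.normal(0, 2.5, 1740)).cumsum() % 10]
        )
        single = compute_odi(make_trace(values))
        double = compute_odi(make_trace(np.concatenate([values, values])))
        for name in ("odi2", "odi3", "odi4t", "odi4a"):
            assert getattr(double, name) == pytest.approx(getattr(single, name), abs=1e-9)

    def test_rate_equals_count_over_valid_hours(self):
        rng = np.random.default_rng(11)
        values = 96 - np.abs(rng.normal(0, 2.5, 3600)).cumsum() % 10
        result = compute_odi(make_trace(values))
        for name, rate in result.as_dict().items():
            if name == "valid_hours":
                continue
            assert rate == pytest.approx(
                len(result.events[name]) / result.valid_hours, abs=1e-9
            )

    def test_total_denominator_smaller_than_valid(self):
        values = np.full(7200, 96.0)
        values[1000:1100] = 90.0
        valid = np.ones(7200, dtype=bool)
        valid[5000:6000] = False
        tr = make_trace(values, valid=valid)
        by_valid = compute_odi(tr, denominator="valid")
        by_total = compute_odi(tr, denominator="total")
        assert by_total.odi4a < by_valid.odi4a
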