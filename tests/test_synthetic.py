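"""Synthetic cohort and trace generator."""

import numpy as np
import pytest

from odisleep.scoring import SEVERITIES
from odisleep.synthetic import (
    AHI_CAP,
    CohortSpec,
    ConfigurationError,
    OximeterModel,
    PlantedEvent,
    apply_beat_averaging,
    cohort_frame,
    generate_cohort,
    largest_remainder_allocation,
    plant_events,
    synthesize_trace,
)


class TestGenerateCohort:
    def test_group_sizes_follow_largest_remainder(self):
        sizes = largest_remainder_allocation(616, (0.117, 0.206, 0.214, 0.463))
        assert sizes.tolist() == [72, 127, 132, 285]

    def test_cohort_counts_match_mix(self):
        recs = generate_cohort(CohortSpec(n_patients=616, seed=3))
        counts = {s: 0 for s in SEVERITIES}
        for r in recs:
            counts[r.severity] += 1
        assert [counts[s] for s in SEVERITIES] == [72, 127, 132, 285]

    def test_degenerate_mix_yields_all_normal(self):
        recs = generate_cohort(
            CohortSpec(n_patients=10, severity_mix=(1.0, 0.0, 0.0, 0.0), seed=1)
        )
        assert len(recs) == 10
        assert all(r.severity == "normal" and r.ahi < 5 for r in recs)

    def test_ahi_always_inside_severity_band(self):
        recs = generate_cohort(CohortSpec(n_patients=120, seed=11))
        bands = {"normal": (0, 5), "mild": (5, 15), "moderate": (15, 30),
                 "severe": (30, AHI_CAP + 1)}
        for r in recs:
            lo, hi = bands[r.severity]
            assert lo <= r.ahi < hi

    def test_fixed_seed_reproducible(self):
        a = cohort_frame(generate_cohort(CohortSpec(n_patients=50, seed=9)))
        b = cohort_frame(generate_cohort(CohortSpec(n_patients=50, seed=9)))
        assert a.equals(b)

    def test_severity_gradients(self):
        """Group means of AHI and arousal index rise with severity."""
        recs = generate_cohort(CohortSpec(n_patients=616, seed=5))
        df = cohort_frame(recs)
        ahi_means = df.groupby("severity")["ahi"].mean()[list(SEVERITIES)]
        assert ahi_means.is_monotonic_increasing
        ai = df.groupby("severity")["arousal_index"].mean()
        assert ai["severe"] > ai["normal"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"severity_mix": (0.5, 0.5, 0.5, 0.5)},
            {"n_patients": 3},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortSpec(seed=0, **kwargs))


class TestPlantEvents:
    def test_event_count_forced_by_rate(self):
        assert len(plant_events(30, 6, seed=4)) == 180

    def test_zero_rate_gives_no_events(self):
        assert plant_events(0, 6, seed=4) == []

    def test_events_never_overlap(self):
        for seed in range(5):
            events = sorted(plant_events(60, 6, seed=seed), key=lambda e: e.onset_s)
            for a, b in zip(events, events[1:]):
                assert a.onset_s + a.duration_s <= b.onset_s

    def test_durations_and_depths_in_contract_ranges(self):
        events = plant_events(40, 6, seed=2)
        assert all(10 <= e.duration_s <= 60 for e in events)
        assert all(e.depth_pct > 0 for e in events)
        assert all(e.kind in ("apnea", "hypopnea") for e in events)
        # hypopneas must carry a >=4-point desaturation by construction
        assert all(e.depth_pct >= 4 for e in events if e.kind == "hypopnea")

    def test_deep_fraction_of_default_mixture(self):
        """Monte-Carlo: at least 80 % of planted events exceed 4 % points depth."""
        deep = total = 0
        for seed in range(20):
            events = plant_events(30, 6, seed=seed)
            deep += sum(e.depth_pct > 4 for e in events)
            total += len(events)
        assert deep / total >= 0.80

    def test_impossible_density_raises_with_limiting_rate(self):
        with pytest.raises(ValueError, match="events/h"):
            plant_events(200, 6, seed=0)


class TestSynthesizeTrace:
    def test_no_events_no_noise_is_constant(self, quiet_model):
        tr = synthesize_trace([], 600, quiet_model, seed=0, resting_pct=97.0)
        assert np.allclose(tr.spo2, 97.0)

    def test_single_event_trough_reaches_planted_depth(self, quiet_model):
        ev = PlantedEvent(onset_s=200, duration_s=20, depth_pct=6.0, kind="apnea")
        tr = synthesize_trace([ev], 600, quiet_model, seed=0, resting_pct=96.0)
        assert tr.spo2.min() == pytest.approx(90.0, abs=0.5)
        # trough sits inside the event window
        assert 200 <= int(tr.spo2.argmin()) < 220

    def test_event_outside_duration_rejected(self, quiet_model):
        ev = PlantedEvent(onset_s=590, duration_s=20, depth_pct=6.0, kind="apnea")
        with pytest.raises(ValueError, match="exceeds trace duration"):
            synthesize_trace([ev], 600, quiet_model, seed=0)

    def test_too_short_recording_rejected(self, quiet_model):
        with pytest.raises(ValueError, match=">= 60"):
            synthesize_trace([], 30, quiet_model, seed=0)

    def test_fixed_seed_reproducible(self):
        events = plant_events(20, 1, seed=8)
        a = synthesize_trace(events, 3600, seed=8)
        b = synthesize_trace(events, 3600, seed=8)
        assert np.array_equal(a.spo2, b.spo2)


class TestBeatAveraging:
    def test_constant_input_is_fixed_point(self):
        x = np.full(100, 95.0)
        y = apply_beat_averaging(x, np.full(100, 70.0))
        assert np.allclose(y, 95.0)

    def test_step_response_closed_form_at_60_bpm(self):
        """With alpha = 1 - exp(-1/window), the response k seconds after a
        step is exactly 1 - exp(-k/window); at 60 bpm the 4-beat window is
        4 s, so 4 s after the step the output sits at the 1 - 1/e level."""
        x = np.concatenate([np.zeros(50), np.ones(100)])
        y = apply_beat_averaging(x, np.full(150, 60.0))
        k = 4  # samples after the step onset; window_s = 4*60/60 = 4
        assert y[50 + k - 1] == pytest.approx(1 - np.exp(-1.0), abs=1e-12)

    def test_window_doubles_above_first_threshold_and_slows_response(self):
        # crossing 112 bpm doubles the beat window; just above the
        # threshold the window in seconds lengthens (8*60/113 > 4*60/60 s),
        # so the step response is strictly slower than at 60 bpm
        x = np.concatenate([np.zeros(50), np.ones(100)])
        slow = apply_beat_averaging(x, np.full(150, 113.0))
        fast = apply_beat_averaging(x, np.full(150, 60.0))
        assert np.all(slow[50:80] < fast[50:80])

    def test_window_redoubles_above_second_threshold(self):
        x = np.concatenate([np.zeros(50), np.ones(100)])
        fast = apply_beat_averaging(x, np.full(150, 225.0))  # 8-beat window
        slow = apply_beat_averaging(x, np.full(150, 226.0))  # 16-beat window
        assert slow[60] < fast[60]

    def test_nonpositive_pulse_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_beat_averaging(np.ones(5), np.array([60, 60, 0, 60, 60.0]))

    def test_model_invariants_validated(self):
        with pytest.raises(ConfigurationError):
            OximeterModel(rate_thresholds=(225.0, 112.0)).validate()
        with pytest.raises(ConfigurationError):
            OximeterModel(noise_sd=-1.0).validate()
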