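"""Synthetic sleep-clinic cohorts and overnight SpO2 traces.

The generator emulates a referral-clinic population of suspected OSA
patients: a four-band severity mix, per-band distributions of age, BMI,
neck circumference (NC), Epworth score (ESS), AHI, sleep architecture
(TST, latency, arousals) and heart rate, plus overnight 1-Hz oximetry
traces whose desaturation-event rate is driven by the patient's true AHI.

The oximeter instrument model mirrors bedside pulse oximeters: the
displayed SpO2 is a beat-windowed exponential average of the underlying
signal (4 beats at ordinary pulse rates, doubled above 112 bpm and again
above 225 bpm), Gaussian measurement noise is added, and two artifact
classes are injected — single-sample downward spikes (slew > 4 %/s) and
probe dropouts (values below 50 %).

Event morphology (the waveform of a planted desaturation) is a package
design choice: linear descent over the first 30 % of the event, a plateau
at full depth, then exponential re-saturation (tau = 5 s) after the event
ends. Overlapping events combine by taking the deeper depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .scoring import SEVERITIES, classify_severity, severity_band
from .trace import SpO2Trace

__all__ = [
    "CohortSpec",
    "OximeterModel",
    "PlantedEvent",
    "PatientRecord",
    "DEFAULT_GROUP_PARAMS",
    "generate_cohort",
    "cohort_frame",
    "plant_events",
    "events_frame",
    "synthesize_trace",
    "apply_beat_averaging",
    "largest_remainder_allocation",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


#: Per-severity (mean, sd) of each cohort variable, in the order
#: normal, mild, moderate, severe. Values describe a tertiary sleep-clinic
#: referral population. AHI draws are additionally resampled until they fall
#: in the band implied by the severity label.
DEFAULT_GROUP_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "age": ((36.2, 10.2), (42.1, 11.5), (45.9, 12.8), (48.4, 12.5)),
    "bmi": ((23.88, 3.15), (25.60, 3.75), (26.18, 3.68), (28.22, 4.33)),
    "nc": ((36.24, 3.25), (37.53, 3.52), (38.69, 3.19), (40.79, 3.10)),
    "ess": ((7.67, 5.16), (8.54, 4.77), (9.19, 5.25), (9.93, 5.34)),
    "ahi": ((2.4, 1.5), (9.6, 2.9), (21.5, 4.3), (52.0, 22.0)),
    "heart_rate": ((70.31, 8.45), (71.05, 10.61), (72.64, 9.50), (75.41, 11.97)),
    "tst_min": ((317.8, 56.3), (331.3, 48.9), (307.6, 58.5), (297.5, 69.8)),
    "latency_min": ((27.6, 33.0), (16.2, 13.6), (22.4, 23.2), (17.9, 18.2)),
    "arousal_index": ((19.3, 10.8), (20.6, 10.1), (26.6, 11.2), (46.3, 21.9)),
}

#: Upper cap on generated AHI (events/h). Non-overlapping events of 10-60 s
#: with 5-s recovery gaps pack at most ~90/h; the cap keeps every generated
#: patient physically renderable as a trace with headroom to spare.
AHI_CAP = 80.0

DEFAULT_SEVERITY_MIX = (0.117, 0.206, 0.214, 0.463)
DEFAULT_FEMALE_FRACTION = (0.444, 0.386, 0.235, 0.102)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic study population."""

    n_patients: int = 616
    severity_mix: tuple[float, float, float, float] = DEFAULT_SEVERITY_MIX
    group_params: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    female_fraction_per_group: tuple[float, ...] = DEFAULT_FEMALE_FRACTION
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be at least 4")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ConfigurationError("severity_mix must sum to 1")
        if any(p < 0 or p > 1 for p in self.severity_mix):
            raise ConfigurationError("severity_mix proportions must lie in [0, 1]")
        if any(p < 0 or p > 1 for p in self.female_fraction_per_group):
            raise ConfigurationError("female fractions must lie in [0, 1]")
        for var, groups in self.group_params.items():
            if len(groups) != len(SEVERITIES):
                raise ConfigurationError(f"{var}: need one (mean, sd) per severity")
            if any(sd < 0 for _, sd in groups):
                raise ConfigurationError(f"{var}: standard deviations must be >= 0")


@dataclass(frozen=True)
class OximeterModel:
    """Instrument model for the simulated pulse oximeter."""

    averaging_beats_base: int = 4
    rate_thresholds: tuple[float, float] = (112.0, 225.0)
    noise_sd: float = 0.35
    artifact_spike_rate: float = 1.0  # events/h
    dropout_rate: float = 0.2  # events/h

    def validate(self) -> None:
        if self.averaging_beats_base < 1:
            raise ConfigurationError("averaging_beats_base must be >= 1")
        if not self.rate_thresholds[0] < self.rate_thresholds[1]:
            raise ConfigurationError("rate_thresholds must be strictly increasing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.artifact_spike_rate < 0 or self.dropout_rate < 0:
            raise ConfigurationError("artifact rates must be >= 0")


@dataclass(frozen=True)
class PlantedEvent:
    """A planted respiratory event with its oximetric footprint."""

    onset_s: int
    duration_s: int
    depth_pct: float
    kind: str  # "apnea" | "hypopnea"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s < 10:
            raise ValueError("respiratory events last at least 10 s")
        if self.depth_pct <= 0:
            raise ValueError("depth_pct must be positive")


@dataclass
class PatientRecord:
    """One synthetic patient: demographics, PSG summary, and truth."""

    patient_id: str
    severity: str
    sex: str
    age: float
    bmi: float
    nc: float
    ess: float
    ahi: float
    heart_rate: float
    tst_min: float
    latency_min: float
    trt_min: float
    arousal_index: float
    arousal_count: int
    seed: int

    @property
    def tst_hours(self) -> float:
        return self.tst_min / 60.0

    @property
    def tst_ge_4h(self) -> bool:
        return self.tst_min >= 240.0


def largest_remainder_allocation(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer group sizes summing to n, by the largest-remainder rule.

    Ties in remainder are broken toward the earlier group, deterministically.
    """
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _ahi_in_band(rng: np.random.Generator, mean: float, sd: float,
                 band: tuple[float, float], max_tries: int = 1000) -> float:
    lo, hi = band
    for _ in range(max_tries):
        draw = rng.normal(mean, sd)
        if lo <= draw < hi:
            return float(draw)
    # distribution barely overlaps the band; fall back to clipping inside it
    edge = min(max(mean, lo), np.nextafter(hi, lo) if np.isfinite(hi) else mean)
    return float(edge)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort of patients per the spec's group distributions.

    Group sizes follow the largest-remainder rounding of ``severity_mix``.
    Each patient's draws come from an own-seeded generator (``spec.seed`` +
    patient index) so the cohort is reproducible patient-by-patient.
    """
    spec.validate()
    sizes = largest_remainder_allocation(spec.n_patients, spec.severity_mix)
    records: list[PatientRecord] = []
    idx = 0
    for g, (severity, size) in enumerate(zip(SEVERITIES, sizes)):
        lo, hi = severity_band(severity)
        band = (lo, min(hi, AHI_CAP))
        for _ in range(size):
            pseed = spec.seed + idx
            rng = np.random.default_rng(pseed)
            gp = {var: spec.group_params[var][g] for var in spec.group_params}
            age = _truncated_normal(rng, *gp["age"], 20.0, 85.0)
            bmi = _truncated_normal(rng, *gp["bmi"], 10.0, 70.0)
            nc = _truncated_normal(rng, *gp["nc"], 20.0, 60.0)
            ess = round(_truncated_normal(rng, *gp["ess"], 0.0, 24.0))
            ahi = _ahi_in_band(rng, *gp["ahi"], band)
            hr = _truncated_normal(rng, *gp["heart_rate"], 40.0, 180.0)
            tst = _truncated_normal(rng, *gp["tst_min"], 61.0, 600.0)
            latency = _truncated_normal(rng, *gp["latency_min"], 0.0, 240.0)
            wake_after = abs(rng.normal(15.0, 10.0))
            ai = _truncated_normal(rng, *gp["arousal_index"], 0.0, 150.0)
            sex = "F" if rng.random() < spec.female_fraction_per_group[g] else "M"
            records.append(
                PatientRecord(
                    patient_id=f"P{idx:04d}",
                    severity=severity,
                    sex=sex,
                    age=age,
                    bmi=bmi,
                    nc=nc,
                    ess=float(ess),
                    ahi=ahi,
                    heart_rate=hr,
                    tst_min=tst,
                    latency_min=latency,
                    trt_min=tst + latency + wake_after,
                    arousal_index=ai,
                    arousal_count=int(round(ai * tst / 60.0)),
                    seed=pseed,
                )
            )
            idx += 1
    assert all(classify_severity(r.ahi) == r.severity for r in records)
    return records


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort table, one row per patient."""
    return pd.DataFrame([vars(r) for r in records])


def plant_events(
    ahi: float,
    tst_hours: float,
    seed: int,
    *,
    deep_fraction: float = 0.85,
    min_gap_s: int = 5,
) -> list[PlantedEvent]:
    """Place round(ahi * tst_hours) non-overlapping respiratory events.

    Durations are uniform on [10, 60] s. Depths follow a two-component
    mixture: with probability ``deep_fraction`` uniform on (6, 13) % points
    (typical of scored desaturations, and clearly detectable even against
    an all-night-mean baseline that the events themselves depress),
    otherwise uniform on (2, 4) (sub-threshold for 4 % indices but visible
    to ODI2/ODI3).
    Events deeper than 4 points are labelled apnea or hypopnea at random;
    shallower ones are apneas (a hypopnea requires >= 4 % desaturation).

    Onsets are uniform over the sleep period conditional on no overlap
    (gaps drawn from a flat Dirichlet over the free time, which is the
    exact conditional distribution); a minimum inter-event gap of
    ``min_gap_s`` seconds leaves room for re-saturation.
    """
    if ahi < 0:
        raise ValueError("ahi must be >= 0")
    if tst_hours <= 0:
        raise ValueError("tst_hours must be positive")
    n = int(round(ahi * tst_hours))
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    total_s = int(round(tst_hours * 3600))
    durations = rng.integers(10, 61, size=n)
    free = total_s - int(durations.sum()) - min_gap_s * (n + 1)
    if free < 0:
        max_rate = total_s / ((durations.mean() + min_gap_s) * tst_hours)
        raise ValueError(
            f"cannot place {n} events without overlap in {tst_hours:.2f} h; "
            f"the limiting event rate is about {max_rate:.1f} events/h"
        )
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    onsets = (np.cumsum(gaps[:-1] + min_gap_s) + np.concatenate(
        [[0], np.cumsum(durations[:-1])])).astype(int)
    deep = rng.random(n) < deep_fraction
    depths = np.where(deep, rng.uniform(6.0, 13.0, n), rng.uniform(2.0, 4.0, n))
    kinds = np.where(
        depths >= 4.0,
        np.where(rng.random(n) < 0.55, "apnea", "hypopnea"),
        "apnea",
    )
    return [
        PlantedEvent(int(o), int(d), float(dp), str(k))
        for o, d, dp, k in zip(onsets, durations, depths, kinds)
    ]


def events_frame(events: Sequence[PlantedEvent], patient_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "depth_pct": [e.depth_pct for e in events],
            "kind": [e.kind for e in events],
        }
    )


def _depression_profile(length: int, events: Sequence[PlantedEvent],
                        recovery_tau_s: float = 5.0) -> np.ndarray:
    """Per-sample depression below resting level; overlaps take the deeper."""
    dep = np.zeros(length)
    t = np.arange(length)
    for ev in events:
        ramp = max(1, int(round(0.3 * ev.duration_s)))
        prof = np.zeros(length)
        start, end = ev.onset_s, ev.onset_s + ev.duration_s  # [start, end)
        descent = np.minimum((t[start:end] - start + 1) / ramp, 1.0)
        prof[start:end] = ev.depth_pct * descent
        tail = np.arange(end, min(length, end + int(8 * recovery_tau_s)))
        if tail.size:
            prof[tail] = ev.depth_pct * np.exp(-(tail - end + 1) / recovery_tau_s)
        np.maximum(dep, prof, out=dep)
    return dep


def apply_beat_averaging(
    raw: SpO2Trace | np.ndarray,
    pulse: np.ndarray,
    model: OximeterModel | None = None,
) -> np.ndarray:
    """Exponential moving average with a beat-count window set by pulse rate.

    The effective window is ``averaging_beats_base`` beats (4) for pulse up
    to the first rate threshold (112 bpm), doubled (8) up to the second
    (225 bpm), and redoubled (16) above it. The window is converted to
    seconds through the instantaneous pulse rate and the per-sample
    smoothing constant is alpha = 1 - exp(-dt / window_s) with dt = 1 s, so
    a step input reaches the (1 - 1/e) level exactly one window after the
    step. A constant input is a fixed point.
    """
    model = model or OximeterModel()
    model.validate()
    x = raw.spo2 if isinstance(raw, SpO2Trace) else np.asarray(raw, dtype=float)
    pulse = np.asarray(pulse, dtype=float)
    if pulse.shape != x.shape:
        raise ValueError("pulse series must have the same length as the trace")
    if np.any(pulse <= 0):
        raise ValueError("pulse rates must be positive")
    lo, hi = model.rate_thresholds
    beats = np.where(pulse <= lo, model.averaging_beats_base,
                     np.where(pulse <= hi, 2 * model.averaging_beats_base,
                              4 * model.averaging_beats_base))
    window_s = beats * 60.0 / pulse
    alpha = 1.0 - np.exp(-1.0 / window_s)
    if np.allclose(alpha, alpha[0]):
        a = float(alpha[0])
        y, _ = lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * x[0]])
        return y
    y = np.empty_like(x)
    acc = x[0]
    for i in range(x.size):
        acc = acc + alpha[i] * (x[i] - acc)
        y[i] = acc
    return y


def synthesize_trace(
    events: Sequence[PlantedEvent],
    duration_s: int,
    model: OximeterModel | None = None,
    seed: int = 0,
    *,
    resting_pct: float | None = None,
    pulse: np.ndarray | None = None,
) -> SpO2Trace:
    """Render a 1-Hz SpO2 trace containing the planted events.

    The clean signal is the resting saturation (drawn uniformly from
    96-98 % unless given) minus the combined event depression profile; the
    instrument response (beat-windowed EMA) is applied, Gaussian noise of
    ``model.noise_sd`` added, then spike and dropout artifacts injected at
    their hourly Poisson rates. Spikes are single-sample downward jumps of
    6-12 points (always above the 50 % dropout floor); dropouts are 1-5 s
    runs of sub-50 values.
    """
    model = model or OximeterModel()
    model.validate()
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 (moving baseline undefined)")
    for ev in events:
        if ev.onset_s + ev.duration_s > duration_s:
            raise ValueError(
                f"event at {ev.onset_s}s (+{ev.duration_s}s) exceeds trace "
                f"duration {duration_s}s"
            )
    rng = np.random.default_rng(seed)
    resting = float(rng.uniform(96.0, 98.0)) if resting_pct is None else resting_pct
    clean = resting - _depression_profile(duration_s, events)
    if pulse is None:
        pulse = np.full(duration_s, 72.0)  # typical clinic mean heart rate
    averaged = apply_beat_averaging(clean, pulse, model)
    noisy = averaged + rng.normal(0.0, model.noise_sd, duration_s)

    hours = duration_s / 3600.0
    n_spikes = rng.poisson(model.artifact_spike_rate * hours)
    if n_spikes:
        # candidate slots >= 3 s apart so each spike sits between clean samples
        slots = np.arange(1, duration_s - 1, 3)
        pos = rng.choice(slots, size=min(n_spikes, slots.size), replace=False)
        drop = rng.uniform(6.0, 12.0, pos.size)
        noisy[pos] = np.maximum(noisy[pos] - drop, 51.0)
    n_drop = rng.poisson(model.dropout_rate * hours)
    for _ in range(n_drop):
        start = int(rng.integers(0, duration_s))
        run = int(rng.integers(1, 6))
        noisy[start : start + run] = rng.uniform(0.0, 45.0)
    return SpO2Trace(spo2=np.clip(noisy, 0.0, 100.0), pulse=pulse)
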