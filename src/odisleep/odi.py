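"""Oxyhemoglobin desaturation index (ODI) computation.

An ODI variant ODI*nb* counts desaturation events of depth >= *n* saturation
percentage points below a baseline *b*, lasting at least 3 s, per hour of
artifact-free recording. Two baselines are supported:

* ``A`` — the all-night mean of the valid saturation samples (a single
  constant);
* ``T`` — at each second, the mean of the top 20 % of valid saturation
  values over the preceding minute (a moving, adaptive baseline that tracks
  the patient's current "awake" ceiling).

The four standard variants are ODI2 and ODI3 (both baseline T), ODI4T and
ODI4A. "n % decrease" is read as an absolute drop of n percentage points,
the standard oximetry convention; a relative (fractional) mode is available
behind the ``relative`` flag.

Numerical conventions, chosen for bit-reproducibility:

* baseline T at time t uses the half-open window [t-60, t) of valid
  samples; with fewer than ``min_window_samples`` (default 12) valid samples
  the baseline is undefined and no event sample may occur there;
* the top-20 % set contains the ceil(0.2 * |W|) largest values of the
  window (ties resolved by value, which is all the mean needs);
* an event is a maximal run of consecutive samples that are valid, have a
  defined baseline, and sit at or below baseline - n; runs shorter than
  ``min_duration_s`` samples are discarded ("minimum of 3 s" at 1 Hz means
  at least 3 qualifying samples; ``strict_gt`` demands strictly more);
* the event boundary is the threshold crossing, not the return to baseline,
  and events separated by even a single recovered sample are not merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import valid_recording_hours
from .trace import SpO2Trace

__all__ = [
    "ODIParams",
    "DesatEvent",
    "ODIResult",
    "baseline_all_night",
    "baseline_top20_preceding",
    "baseline_series",
    "detect_events",
    "compute_odi",
]

BaselineMode = Literal["A", "T"]

#: (index name, threshold % points, baseline mode) of the four variants.
ODI_VARIANTS: tuple[tuple[str, float, BaselineMode], ...] = (
    ("odi2", 2.0, "T"),
    ("odi3", 3.0, "T"),
    ("odi4t", 4.0, "T"),
    ("odi4a", 4.0, "A"),
)


@dataclass(frozen=True)
class ODIParams:
    """Detection parameters for one ODI variant."""

    threshold_n: float
    baseline_mode: BaselineMode = "T"
    min_duration_s: int = 3
    min_window_samples: int = 12
    strict_gt: bool = False
    relative: bool = False

    def __post_init__(self) -> None:
        if self.threshold_n <= 0:
            raise ValueError("threshold_n must be positive")
        if self.min_duration_s < 1:
            raise ValueError("min_duration_s must be >= 1")
        if self.baseline_mode not in ("A", "T"):
            raise ValueError("baseline_mode must be 'A' or 'T'")


@dataclass(frozen=True)
class DesatEvent:
    """One detected desaturation episode (inclusive 1-Hz sample run)."""

    start_s: int
    end_s: int
    nadir_pct: float
    threshold_used: float

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s + 1


@dataclass
class ODIResult:
    """The four desaturation indices for one recording."""

    odi2: float
    odi3: float
    odi4t: float
    odi4a: float
    valid_hours: float
    events: dict[str, list[DesatEvent]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: len(evs) for name, evs in self.events.items()}

    def as_dict(self) -> dict[str, float]:
        return {
            "odi2": self.odi2,
            "odi3": self.odi3,
            "odi4t": self.odi4t,
            "odi4a": self.odi4a,
            "valid_hours": self.valid_hours,
        }


def baseline_all_night(trace: SpO2Trace) -> np.ndarray:
    """Baseline A: constant series equal to the mean of all valid samples."""
    if not trace.valid.any():
        raise ValueError("no valid samples; all-night baseline undefined")
    mean = float(trace.spo2[trace.valid].mean())
    return np.full(len(trace), mean)


def baseline_top20_preceding(
    trace: SpO2Trace, t_s: int, *, min_window_samples: int = 12
) -> float | None:
    """Baseline T at one second: mean of the top 20 % of valid values in
    [t_s - 60, t_s), or None when fewer than ``min_window_samples`` valid
    samples precede."""
    if not (0 <= t_s < len(trace)):
        raise ValueError(f"t_s={t_s} outside trace of length {len(trace)}")
    lo = max(0, t_s - 60)
    window = trace.spo2[lo:t_s][trace.valid[lo:t_s]]
    if window.size < min_window_samples:
        return None
    k = int(np.ceil(0.2 * window.size))
    top = np.sort(window)[-k:]
    return float(top.mean())


def baseline_series(
    trace: SpO2Trace, mode: BaselineMode, *, min_window_samples: int = 12
) -> np.ndarray:
    """Per-sample baseline; NaN where undefined (mode T early samples /
    sparse windows)."""
    if mode == "A":
        return baseline_all_night(trace)
    x = np.where(trace.valid, trace.spo2, np.nan)
    pad = np.full(60, np.nan)
    xp = np.concatenate([pad, x])
    # row t is xp[t : t+60] == x[t-60 : t), the preceding minute
    win = sliding_window_view(xp, 60)[: x.size]
    cnt = np.sum(~np.isnan(win), axis=1)
    filled = np.where(np.isnan(win), -np.inf, win)
    desc = -np.sort(-filled, axis=1)  # descending, -inf (missing) last
    k = np.maximum(np.ceil(0.2 * cnt).astype(int), 1)
    csum = np.cumsum(desc, axis=1)
    top_mean = np.take_along_axis(csum, (k - 1)[:, None], axis=1)[:, 0] / k
    return np.where(cnt >= min_window_samples, top_mean, np.nan)


def detect_events(
    trace: SpO2Trace, params: ODIParams, *, baseline: np.ndarray | None = None
) -> list[DesatEvent]:
    """Find maximal sub-threshold runs of qualifying duration.

    ``baseline`` lets callers reuse a precomputed baseline series when
    scanning one trace at several thresholds.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if baseline is None:
        baseline = baseline_series(
            trace, params.baseline_mode, min_window_samples=params.min_window_samples
        )
    if params.relative:
        limit = baseline * (1.0 - params.threshold_n / 100.0)
    else:
        limit = baseline - params.threshold_n
    below = trace.valid & ~np.isnan(baseline) & (trace.spo2 <= limit)

    # maximal runs of True
    padded = np.concatenate([[False], below, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive ends
    min_len = params.min_duration_s + (1 if params.strict_gt else 0)
    events = []
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_len:
            nadir = float(trace.spo2[s : e + 1].min())
            events.append(DesatEvent(int(s), int(e), nadir, params.threshold_n))
    return events


def compute_odi(
    trace: SpO2Trace,
    *,
    min_duration_s: int = 3,
    min_window_samples: int = 12,
    strict_gt: bool = False,
    relative: bool = False,
    denominator: Literal["valid", "total"] = "valid",
) -> ODIResult:
    """Compute ODI2, ODI3, ODI4T and ODI4A for one (artifact-masked) trace.

    ``denominator`` selects the per-hour normalisation: ``"valid"`` divides
    by artifact-free recording time (default), ``"total"`` by the full
    recording length.
    """
    if denominator == "valid":
        hours = valid_recording_hours(trace)
    elif denominator == "total":
        hours = len(trace) / 3600.0
    else:
        raise ValueError("denominator must be 'valid' or 'total'")

    baselines = {
        mode: baseline_series(trace, mode, min_window_samples=min_window_samples)
        for mode in ("A", "T")
    }
    events: dict[str, list[DesatEvent]] = {}
    rates: dict[str, float] = {}
    for name, n, mode in ODI_VARIANTS:
        params = ODIParams(
            threshold_n=n,
            baseline_mode=mode,
            min_duration_s=min_duration_s,
            min_window_samples=min_window_samples,
            strict_gt=strict_gt,
            relative=relative,
        )
        evs = detect_events(trace, params, baseline=baselines[mode])
        events[name] = evs
        rates[name] = len(evs) / hours
    return ODIResult(
        odi2=rates["odi2"],
        odi3=rates["odi3"],
        odi4t=rates["odi4t"],
        odi4a=rates["odi4a"],
        valid_hours=hours,
        events=events,
    )
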