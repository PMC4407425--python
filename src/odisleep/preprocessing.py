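"""Trace loading, artifact elimination, recording time, and cohort exclusions.

Two automated artifact rules are applied to raw oximetry:

* any saturation value below 50 % is physiologically implausible and masked;
* a change of more than 4 % points between consecutive 1-s samples (4 %/s)
  is faster than real desaturation dynamics and the later sample of the
  offending pair is masked.

Samples are masked, never deleted, so the time axis is preserved. Sub-50
samples are treated as missing before the slew-rate check, i.e. the 4 %/s
rule compares each remaining sample against the nearest preceding sample
that was not a dropout; a sample flagged only by the slew-rate rule still
participates in the following comparison, so a genuine step contaminates
its recovery sample as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trace import SpO2Trace

__all__ = [
    "SleepSummary",
    "ExclusionRules",
    "Exclusion",
    "remove_artifacts",
    "valid_recording_hours",
    "apply_exclusions",
]

SPO2_FLOOR_PCT = 50.0
MAX_SLEW_PCT_PER_S = 4.0


@dataclass(frozen=True)
class SleepSummary:
    """PSG-derived sleep architecture summary for one patient."""

    trt_min: float
    tst_min: float
    latency_min: float
    arousal_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.tst_min <= self.trt_min):
            raise ValueError("need 0 <= TST <= TRT")
        if self.latency_min < 0 or self.arousal_count < 0:
            raise ValueError("latency and arousal count must be non-negative")

    @property
    def sleep_efficiency(self) -> float:
        """TST divided by total recording time."""
        return self.tst_min / self.trt_min if self.trt_min > 0 else 0.0

    @property
    def arousal_index(self) -> float:
        """Arousals per hour of sleep."""
        return self.arousal_count / (self.tst_min / 60.0)


def remove_artifacts(trace: SpO2Trace) -> SpO2Trace:
    """Apply the two automated artifact rules; returns a re-masked copy.

    Values are unchanged; only the validity mask tightens. Idempotent: the
    flag pattern is a pure function of the saturation values, so a second
    application returns the same mask.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    x = trace.spo2
    low = x < SPO2_FLOOR_PCT
    keep = np.flatnonzero(~low)
    jump = np.zeros(x.size, dtype=bool)
    if keep.size > 1:
        big = np.abs(np.diff(x[keep])) > MAX_SLEW_PCT_PER_S
        jump[keep[1:]] = big
    return trace.replace(valid=trace.valid & ~low & ~jump)


def valid_recording_hours(trace: SpO2Trace) -> float:
    """Artifact-free recording time in hours (valid samples / 3600)."""
    n_valid = int(trace.valid.sum())
    if n_valid == 0:
        raise ValueError("trace has no valid samples")
    return n_valid / 3600.0


@dataclass(frozen=True)
class ExclusionRules:
    """Cohort filtering thresholds.

    Records are excluded when total recording time is under 3 h, total sleep
    time under 1 h, or age outside [20, 85]. Records with TST under 4 h are
    *flagged* (not removed) so that the TST>=4h sub-cohort can be formed from
    the same pass.
    """

    min_trt_min: float = 180.0
    min_tst_min: float = 60.0
    age_range: tuple[float, float] = (20.0, 85.0)
    flag_tst_min: float = 240.0


@dataclass(frozen=True)
class Exclusion:
    record: object
    reason: str


def apply_exclusions(
    cohort: Iterable, rules: ExclusionRules | None = None
) -> tuple[list, list[Exclusion]]:
    """Partition a cohort into kept records and labelled exclusions.

    Each record must expose ``trt_min``, ``tst_min`` and ``age``. Each
    exclusion carries the first matching reason in order: ``trt_lt_3h``,
    ``tst_lt_1h``, ``age``. Kept records with ``tst_min`` below
    ``rules.flag_tst_min`` remain kept but fall outside the TST>=4h subset
    (see :func:`tst_subset`).
    """
    rules = rules or ExclusionRules()
    kept: list = []
    excluded: list[Exclusion] = []
    for rec in cohort:
        if rec.trt_min < rules.min_trt_min:
            excluded.append(Exclusion(rec, "trt_lt_3h"))
        elif rec.tst_min < rules.min_tst_min:
            excluded.append(Exclusion(rec, "tst_lt_1h"))
        elif not (rules.age_range[0] <= rec.age <= rules.age_range[1]):
            excluded.append(Exclusion(rec, "age"))
        else:
            kept.append(rec)
    return kept, excluded


def tst_subset(kept: Sequence, rules: ExclusionRules | None = None) -> list:
    """The sub-cohort with TST at or above the flag threshold (default 4 h)."""
    rules = rules or ExclusionRules()
    return [rec for rec in kept if rec.tst_min >= rules.flag_tst_min]
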