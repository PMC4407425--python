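"""Reference-standard sleep scoring quantities.

Polysomnography (PSG) is the gold standard against which oximetry indices
are validated. This module computes the PSG-side quantities from pre-scored
event lists: the apnea-hypopnea index (AHI, respiratory events per hour of
sleep), the arousal index, and the conventional four-band severity class.

Severity bands (left-closed, per standard clinical convention):
normal AHI < 5, mild 5 <= AHI < 15, moderate 15 <= AHI < 30, severe AHI >= 30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SEVERITIES",
    "SEVERITY_BOUNDS",
    "RespiratoryEvent",
    "compute_ahi",
    "classify_severity",
    "severity_band",
    "arousal_index",
]

SEVERITIES: tuple[str, ...] = ("normal", "mild", "moderate", "severe")

#: AHI half-open interval [lo, hi) per severity class.
SEVERITY_BOUNDS: dict[str, tuple[float, float]] = {
    "normal": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, float("inf")),
}

APNEA_KINDS = ("central", "mixed", "obstructive")


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored apnea or hypopnea.

    ``kind`` is ``"apnea"`` (optionally qualified central/mixed/obstructive)
    or ``"hypopnea"``. Both require >= 10 s duration; a hypopnea additionally
    requires an accompanying oxyhemoglobin desaturation of >= 4 % points.
    """

    kind: str
    onset_s: float
    duration_s: float
    desat_pct: float | None = None

    def validate(self) -> None:
        base = self.kind.split(":")[0]
        if base not in ("apnea", "hypopnea"):
            raise ValueError(f"unknown respiratory event kind {self.kind!r}")
        if self.duration_s < 10:
            raise ValueError(
                f"{self.kind} at {self.onset_s:.0f}s lasts {self.duration_s:.1f}s; "
                "respiratory events require a minimum of 10 s"
            )
        if base == "hypopnea":
            if self.desat_pct is None or self.desat_pct < 4:
                raise ValueError(
                    f"hypopnea at {self.onset_s:.0f}s requires a desaturation "
                    f">= 4 % points (got {self.desat_pct})"
                )


def compute_ahi(events: Iterable[RespiratoryEvent], tst_hours: float) -> float:
    """Apneas plus hypopneas per hour of sleep."""
    if tst_hours <= 0:
        raise ValueError("tst_hours must be positive")
    events = list(events)
    for ev in events:
        ev.validate()
    return len(events) / tst_hours


def classify_severity(ahi: float) -> str:
    """Map an AHI to its severity band; boundaries 5/15/30 are inclusive upward."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    for label in reversed(SEVERITIES):
        if ahi >= SEVERITY_BOUNDS[label][0]:
            return label
    return "normal"  # pragma: no cover - ahi >= 0 always matches "normal"


def severity_band(label: str) -> tuple[float, float]:
    """The half-open AHI interval [lo, hi) of a severity label."""
    try:
        return SEVERITY_BOUNDS[label]
    except KeyError:
        raise ValueError(f"unknown severity label {label!r}") from None


def arousal_index(count: int, tst_hours: float) -> float:
    """EEG arousals per hour of sleep."""
    if tst_hours <= 0:
        raise ValueError("tst_hours must be positive")
    if count < 0:
        raise ValueError("arousal count cannot be negative")
    return count / tst_hours


def binary_labels(severities: Sequence[str], task: str) -> list[int]:
    """Binary screening labels: ``severe`` = AHI>=30 positive; ``mod_severe``
    = AHI>=15 positive."""
    if task == "severe":
        positive = {"severe"}
    elif task == "mod_severe":
        positive = {"moderate", "severe"}
    else:
        raise ValueError(f"unknown task {task!r}; expected 'severe' or 'mod_severe'")
    return [1 if s in positive else 0 for s in severities]
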