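"""1-Hz SpO2 trace container.

The whole pipeline operates on overnight pulse-oximetry recordings sampled
at 1 Hz. A trace carries the saturation series (percent, 0-100), an optional
pulse-rate series (bpm), and a boolean validity mask; artifact removal masks
samples rather than deleting them so the time axis stays intact and event
durations remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpO2Trace"]


@dataclass
class SpO2Trace:
    """An overnight SpO2 recording sampled at 1 Hz starting at t=0 s.

    Parameters
    ----------
    spo2 : array of float
        Saturation in percent on the 0-100 scale; clipped into [0, 100].
    pulse : array of float, optional
        Pulse rate in beats per minute, same length as ``spo2``.
    valid : array of bool, optional
        Per-sample validity mask; defaults to all-valid.
    """

    spo2: np.ndarray
    pulse: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spo2 = np.clip(np.asarray(self.spo2, dtype=float), 0.0, 100.0)
        if self.spo2.ndim != 1:
            raise ValueError("spo2 must be one-dimensional")
        if self.pulse is not None:
            self.pulse = np.asarray(self.pulse, dtype=float)
            if self.pulse.shape != self.spo2.shape:
                raise ValueError("pulse series length must match spo2")
        if self.valid is None:
            self.valid = np.ones(self.spo2.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.spo2.shape:
                raise ValueError("valid mask length must match spo2")

    def __len__(self) -> int:
        return self.spo2.size

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds (0, 1, 2, ...)."""
        return np.arange(self.spo2.size)

    @property
    def duration_s(self) -> int:
        return int(self.spo2.size)

    def replace(self, **kwargs) -> "SpO2Trace":
        """Return a copy with the given arrays swapped in."""
        data = {
            "spo2": self.spo2.copy(),
            "pulse": None if self.pulse is None else self.pulse.copy(),
            "valid": self.valid.copy(),
        }
        data.update(kwargs)
        return SpO2Trace(**data)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "spo2_pct": self.spo2})
        df["pulse_bpm"] = self.pulse if self.pulse is not None else np.nan
        df["valid"] = self.valid.astype(int)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpO2Trace":
        if "spo2_pct" not in df.columns:
            raise ValueError("trace table needs a 'spo2_pct' column")
        t = df["time_s"].to_numpy()
        if t.size == 0:
            raise ValueError("empty trace")
        if t[0] != 0 or np.any(np.diff(t) != 1):
            raise ValueError("time_s must start at 0 and advance in 1-s steps")
        pulse = None
        if "pulse_bpm" in df.columns and not df["pulse_bpm"].isna().all():
            pulse = df["pulse_bpm"].to_numpy(dtype=float)
        valid = None
        if "valid" in df.columns:
            valid = df["valid"].to_numpy().astype(bool)
        return cls(spo2=df["spo2_pct"].to_numpy(dtype=float), pulse=pulse, valid=valid)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpO2Trace":
        return cls.from_frame(pd.read_csv(path))
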