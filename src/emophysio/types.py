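"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STAGES = ("baseline", "stimulus", "rest", "recall")
CATEGORIES = (
    "anger",
    "disgust",
    "fear",
    "happiness",
    "neutral",
    "sadness",
    "surprise",
)
METHODS = ("image", "recall", "none")


@dataclass
class SignalRecord:
    """Uniformly sampled 1-D signal.

    Values may contain NaN before cleaning.  ``t0`` is the time of the first
    sample in seconds from session start.  ``meta`` carries generator truth
    and processing provenance; it is never required by the algorithms.
    """

    values: np.ndarray
    fs: float
    channel: str = "signal"
    units: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("SignalRecord values must be 1-D")
        if self.values.size < 2:
            raise ValueError("SignalRecord needs at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def copy_with(self, values: np.ndarray, fs: Optional[float] = None) -> "SignalRecord":
        return SignalRecord(
            values=np.asarray(values, dtype=float),
            fs=self.fs if fs is None else fs,
            channel=self.channel,
            units=self.units,
            t0=self.t0,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class SegmentAnnotation:
    """Labeled half-open interval [start_s, end_s) within a session."""

    start_s: float
    end_s: float
    stage: str
    category: str = "none"
    method: str = "none"
    sam: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.sam is not None and not 1 <= int(self.sam) <= 9:
            raise ValueError(f"sam must be in 1..9, got {self.sam}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_emotion(self) -> bool:
        return self.stage in ("stimulus", "recall")


@dataclass(frozen=True)
class TriggerMark:
    time: float
    source: str = "predicted"  # {predicted, ground_truth}


@dataclass
class RRSeries:
    """R-peak times (s, strictly increasing) and inter-beat intervals (ms)."""

    peak_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.peak_times.size >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if self.intervals.size != max(self.peak_times.size - 1, 0):
            raise ValueError("intervals length must be peaks - 1")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")

    @classmethod
    def from_peak_times(cls, peak_times: np.ndarray) -> "RRSeries":
        pt = np.asarray(peak_times, dtype=float)
        return cls(peak_times=pt, intervals=np.diff(pt) * 1000.0)

    def __len__(self) -> int:
        return int(self.intervals.size)


HRV_FEATURE_NAMES = ("rmssd", "sdnn", "rr_avg", "hr", "hf", "lf", "vlf", "hf2lf")


@dataclass(frozen=True)
class HRVFeatureVector:
    """The 8 per-segment features: 4 time-domain, 4 frequency-domain."""

    rmssd: float
    sdnn: float
    rr_avg: float
    hr: float
    hf: float
    lf: float
    vlf: float
    hf2lf: float  # NaN when LF == 0 (imputed at normalization)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HRV_FEATURE_NAMES], dtype=float)


@dataclass
class Periodogram:
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.size != self.power.size:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
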