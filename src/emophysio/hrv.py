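"""Heart-rate-variability features: four time-domain measures and three
frequency-band powers plus their ratio from a Lomb-Scargle periodogram of the
(unevenly sampled) RR tachogram.

Conventions, kept deliberately explicit because several published variants
exist:

* SDNN uses the population (1/N) normalization.
* Band powers are plain sums of periodogram values over grid points strictly
  inside the band (exclusive limits).
* HF2LF is NaN when LF power is zero; NaN features are imputed with the
  training-column median inside :class:`FeatureScaler`.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import lombscargle

from .types import HRV_FEATURE_NAMES, HRVFeatureVector, Periodogram, RRSeries

log = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {
    "HF": (0.15, 0.40),
    "LF": (0.04, 0.15),
    "VLF": (0.003, 0.04),
}

FREQ_GRID_MIN_HZ = 0.003
FREQ_GRID_MAX_HZ = 0.40
FREQ_GRID_POINTS = 512


def rmssd(rr: RRSeries) -> float:
    """Root mean square of successive RR differences, in ms."""
    x = rr.intervals
    if x.size < 2:
        raise ValueError("rmssd requires at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.sum(d**2) / (x.size - 1)))


def sdnn(rr: RRSeries) -> float:
    """Population standard deviation (1/N) of the RR intervals, in ms."""
    x = rr.intervals
    if x.size < 2:
        raise ValueError("sdnn requires at least 2 intervals")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def rr_avg_and_hr(rr: RRSeries) -> tuple[float, float]:
    """Mean RR interval (ms) and heart rate 60000/mean (bpm)."""
    x = rr.intervals
    if x.size < 1:
        raise ValueError("rr_avg_and_hr requires at least 1 interval")
    mu = float(x.mean())
    return mu, 60000.0 / mu


def frequency_grid(n_points: int = FREQ_GRID_POINTS) -> np.ndarray:
    return np.geomspace(FREQ_GRID_MIN_HZ, FREQ_GRID_MAX_HZ, n_points)


def lomb_scargle(rr: RRSeries, n_points: int = FREQ_GRID_POINTS) -> Periodogram:
    """Lomb-Scargle periodogram of the RR tachogram.

    Sample points are (peak time of the interval's end, interval in ms); the
    series is mean-centered before estimation.  The grid is log-spaced over
    0.003-0.4 Hz.
    """
    if len(rr) < 4:
        raise ValueError("lomb_scargle requires at least 4 intervals")
    t = rr.peak_times[1:]
    y = rr.intervals - rr.intervals.mean()
    freqs = frequency_grid(n_points)
    # classical (unnormalized) periodogram: its expected level is invariant to
    # the segment length, so 30 s and 60 s windows yield comparable band sums
    power = lombscargle(t, y, 2 * np.pi * freqs, normalize=False)
    return Periodogram(frequencies=freqs, power=np.maximum(power, 0.0))


def band_power(p: Periodogram, band: str) -> float:
    """Sum of periodogram values at grid points strictly inside the band."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    if p.frequencies[0] > lo or p.frequencies[-1] < hi:
        raise ValueError(f"periodogram grid does not cover band {band} [{lo}, {hi}]")
    inside = (p.frequencies > lo) & (p.frequencies < hi)
    return float(np.sum(p.power[inside]))


def feature_vector(rr: RRSeries) -> HRVFeatureVector:
    """Assemble the 8-feature vector for one cleaned segment."""
    mu, hr = rr_avg_and_hr(rr)
    per = lomb_scargle(rr)
    hf = band_power(per, "HF")
    lf = band_power(per, "LF")
    vlf = band_power(per, "VLF")
    if lf > 0:
        hf2lf = hf / lf
    else:
        log.warning("feature_vector: LF power is 0; HF2LF reported as missing")
        hf2lf = float("nan")
    return HRVFeatureVector(
        rmssd=rmssd(rr),
        sdnn=sdnn(rr),
        rr_avg=mu,
        hr=hr,
        hf=hf,
        lf=lf,
        vlf=vlf,
        hf2lf=hf2lf,
    )


class FeatureScaler:
    """Per-feature-column min-max scaler fitted on the training partition.

    Transformed values are clipped to [0, 1]; zero-range columns map to 0
    with a warning; NaN entries are imputed with the training-column median.
    """

    def __init__(self) -> None:
        self.col_min: np.ndarray | None = None
        self.col_range: np.ndarray | None = None
        self.col_median: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "FeatureScaler":
        m = np.asarray(matrix, dtype=float)
        if np.isinf(m).any():
            raise ValueError("feature matrix contains infinities")
        self.col_median = np.nanmedian(m, axis=0)
        filled = np.where(np.isnan(m), self.col_median, m)
        self.col_min = filled.min(axis=0)
        self.col_range = filled.max(axis=0) - self.col_min
        if np.any(self.col_range == 0):
            log.warning(
                "FeatureScaler: %d zero-range column(s) mapped to 0",
                int(np.sum(self.col_range == 0)),
            )
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.col_min is None:
            raise RuntimeError("FeatureScaler must be fitted before transform")
        m = np.asarray(matrix, dtype=float)
        m = np.where(np.isnan(m), self.col_median, m)
        rng = np.where(self.col_range == 0, 1.0, self.col_range)
        out = (m - self.col_min) / rng
        out[:, self.col_range == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


def normalize_features(matrix: np.ndarray) -> np.ndarray:
    """Min-max scale each feature column of ``matrix`` to [0, 1].

    Convenience wrapper fitting and applying on the same matrix; for proper
    train/test handling use :class:`FeatureScaler` directly.
    """
    return FeatureScaler().fit_transform(matrix)


FEATURE_NAMES = HRV_FEATURE_NAMES
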