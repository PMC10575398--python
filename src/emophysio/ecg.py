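"""ECG branch: down-sampling, segmentation, raw outlier removal, R-peak and
RR-interval extraction, and RR-series cleaning.

Raw outlier removal follows a sliding min/max window rule: windows whose
minimum (maximum) exceeds ``k`` times the mean window minimum (maximum) are
replaced by the nearest untagged window, preferring the predecessor.  RR
cleaning applies a generalized extreme Studentized deviate (GESD) test and
fills flagged intervals with modified Akima cubic Hermite interpolation.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import Akima1DInterpolator
from scipy.stats import t as t_dist

from .types import RRSeries, SegmentAnnotation, SignalRecord

log = logging.getLogger(__name__)


class UnusableSegmentError(ValueError):
    """Raised when a segment cannot yield usable data (discarded upstream)."""


def downsample(ecg: SignalRecord, target_fs: float = 256.0) -> SignalRecord:
    """Anti-alias filter and decimate to ``target_fs`` (must divide fs)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    factor = ecg.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} must divide fs {ecg.fs} (factor {factor:.3f})"
        )
    q = int(round(factor))
    if q == 1:
        return ecg.copy_with(ecg.values.copy())
    out = sps.decimate(ecg.values, q, n=8, ftype="iir", zero_phase=True)
    return ecg.copy_with(out, fs=target_fs)


def segment_session(
    ecg: SignalRecord, segments: Sequence[SegmentAnnotation]
) -> list[tuple[SegmentAnnotation, SignalRecord]]:
    """Cut one snippet per annotation; sample range [floor(start*fs), floor(end*fs))."""
    span = ecg.t0 + ecg.values.size / ecg.fs
    ordered = sorted(segments, key=lambda a: a.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError(f"overlapping annotations at {b.start_s:.2f}s")
    out = []
    for ann in segments:
        if ann.start_s < ecg.t0 - 1e-9 or ann.end_s > span + 1e-6:
            raise ValueError(
                f"annotation [{ann.start_s}, {ann.end_s}) outside signal span"
            )
        i0 = int(math.floor((ann.start_s - ecg.t0) * ecg.fs))
        i1 = int(math.floor((ann.end_s - ecg.t0) * ecg.fs))
        i1 = min(i1, ecg.values.size)
        snip = SignalRecord(
            values=ecg.values[i0:i1].copy(),
            fs=ecg.fs,
            channel=ecg.channel,
            units=ecg.units,
            t0=ecg.t0 + i0 / ecg.fs,
            meta=dict(ecg.meta),
        )
        out.append((ann, snip))
    return out


def remove_raw_outliers(
    snippet: SignalRecord,
    window_s: float = 1.0,
    stride_s: float = 1.0,
    k: float = 2.5,
) -> SignalRecord:
    """Sliding min/max window outlier removal on the raw ECG snippet.

    Per window the min and max are extracted; a window is tagged when its min
    is below ``k`` times the mean window min (minima are negative, so "below"
    means more negative) or its max exceeds ``k`` times the mean window max.
    Each tagged window is replaced by the nearest untagged window of the
    input, preferring the predecessor at equal distance.  Signal length is
    unchanged; trailing samples that do not fill a window are untouched.
    """
    w = int(round(window_s * snippet.fs))
    stride = int(round(stride_s * snippet.fs))
    if w < 1 or stride < 1:
        raise ValueError("window and stride must be at least one sample")
    if stride != w:
        raise ValueError("only non-overlapping windows (stride == window) supported")
    n_win = snippet.values.size // w
    if n_win < 2:
        raise ValueError("snippet shorter than 2 windows")
    x = snippet.values
    wins = x[: n_win * w].reshape(n_win, w)
    mins = wins.min(axis=1)
    maxs = wins.max(axis=1)
    mean_min = mins.mean()
    mean_max = maxs.mean()
    tagged = np.zeros(n_win, dtype=bool)
    if mean_min < 0:
        tagged |= mins < k * mean_min
    if mean_max > 0:
        tagged |= maxs > k * mean_max
    if tagged.all():
        raise UnusableSegmentError("all windows tagged as outliers")
    out = x.copy()
    untagged = np.flatnonzero(~tagged)
    for i in np.flatnonzero(tagged):
        # nearest untagged window, predecessor preferred on ties
        j = untagged[np.argmin(np.abs(untagged - i) * 2 + (untagged > i))]
        out[i * w : (i + 1) * w] = x[j * w : (j + 1) * w]
    rec = snippet.copy_with(out)
    rec.meta["tagged_windows"] = np.flatnonzero(tagged)
    return rec


def detect_r_peaks(snippet: SignalRecord, refractory_s: float = 0.2) -> RRSeries:
    """Pan-Tompkins-style R-peak detection on a cleaned 256 Hz snippet.

    Band-pass (5-15 Hz), differentiate, square, moving-window integrate, pick
    peaks with an adaptive threshold and a refractory constraint, then refine
    each peak to the local maximum of the raw signal.
    """
    fs = snippet.fs
    x = snippet.values
    if not np.all(np.isfinite(x)):
        raise ValueError("snippet contains non-finite values")
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filt = sps.filtfilt(b, a, x)
    deriv = np.gradient(filt)
    squared = deriv**2
    win = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(squared, np.ones(win) / win, mode="same")
    distance = max(int(round(refractory_s * fs)), 1)
    cand, props = sps.find_peaks(integ, distance=distance)
    if cand.size < 2:
        raise UnusableSegmentError("fewer than 2 R peaks found")
    heights = integ[cand]
    thresh = 0.3 * np.median(heights[heights > 0.1 * heights.max()])
    cand = cand[integ[cand] >= thresh]
    if cand.size < 2:
        raise UnusableSegmentError("fewer than 2 R peaks above threshold")
    # refine to raw-signal local maximum (R wave dominates within +-80 ms)
    half = int(round(0.08 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after refinement
    keep = [peaks[0]]
    for p in peaks[1:]:
        if p - keep[-1] >= distance:
            keep.append(p)
        elif x[p] > x[keep[-1]]:
            keep[-1] = p
    times = snippet.t0 + np.asarray(keep, dtype=float) / fs
    if times.size < 2:
        raise UnusableSegmentError("fewer than 2 R peaks after refinement")
    return RRSeries.from_peak_times(times)


def gesd_outliers(
    x: np.ndarray, alpha: float = 0.05, max_outliers: int | None = None
) -> np.ndarray:
    """Indices flagged by the generalized extreme Studentized deviate test."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(int(math.ceil(0.1 * n)), 1)
    max_outliers = min(max_outliers, n - 2)
    if n < 3 or max_outliers < 1:
        return np.array([], dtype=int)
    idx = np.arange(n)
    mask = np.ones(n, dtype=bool)
    removed: list[int] = []
    n_out = 0
    for i in range(1, max_outliers + 1):
        xs = x[mask]
        mu, sd = xs.mean(), xs.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(xs - mu)
        j = int(np.argmax(dev))
        r_stat = dev[j] / sd
        m = xs.size
        p = 1.0 - alpha / (2.0 * m)
        tc = t_dist.ppf(p, m - 2)
        lam = (m - 1) * tc / math.sqrt((m - 2 + tc**2) * m)
        removed.append(int(idx[mask][j]))
        mask[idx[mask][j]] = False
        if r_stat > lam:
            n_out = i
    return np.asarray(removed[:n_out], dtype=int)


def clean_rr(
    rr: RRSeries, alpha: float = 0.05, max_outlier_frac: float = 0.1
) -> RRSeries:
    """GESD outlier removal on the RR interval sequence with modified Akima fill.

    Flagged intervals are replaced by modified Akima cubic Hermite
    interpolation over interval index; peak times are rebuilt from the first
    retained peak so the RRSeries invariant holds.
    """
    n = len(rr)
    if n < 5:
        log.warning("clean_rr: %d intervals < 5, returned unchanged", n)
        return rr
    intervals = rr.intervals.copy()
    flagged = gesd_outliers(
        intervals, alpha=alpha, max_outliers=int(math.ceil(max_outlier_frac * n))
    )
    if flagged.size == 0:
        return RRSeries(rr.peak_times.copy(), intervals)
    good = np.setdiff1d(np.arange(n), flagged)
    if good.size < 2:
        log.warning("clean_rr: too few clean intervals to interpolate")
        return rr
    interp = Akima1DInterpolator(good.astype(float), intervals[good], method="makima")
    filled = interp(flagged.astype(float), extrapolate=True)
    # out-of-hull edges: nearest clean value is more stable than extrapolation
    lo, hi = good[0], good[-1]
    filled = np.where(flagged < lo, intervals[good[0]], filled)
    filled = np.where(flagged > hi, intervals[good[-1]], filled)
    intervals[flagged] = filled
    peak_times = rr.peak_times[0] + np.concatenate(
        [[0.0], np.cumsum(intervals) / 1000.0]
    )
    return RRSeries(peak_times, intervals)


def session_usable(segment_flags: Sequence[bool], max_bad_frac: float = 0.2) -> bool:
    """Discard rule: a session is unusable when > 20% of segments failed."""
    flags = list(segment_flags)
    if not flags:
        return False
    return sum(1 for f in flags if not f) <= max_bad_frac * len(flags)
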