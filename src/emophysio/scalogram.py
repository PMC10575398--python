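"""Continuous wavelet transform scalograms of ECG snippets.

The transform uses an analytic complex Morlet wavelet evaluated in the
frequency domain,

    psi_hat(w) = exp(-B * (w - 2*pi*fc)^2 / 4)   for w > 0, else 0,

i.e. the Fourier transform of (pi*B)^(-1/2) * exp(-t^2/B) * exp(2i*pi*fc*t).
``B`` is the time-bandwidth parameter (default 0.234) and ``fc`` the center
frequency in cycles/sample (default 1.0).  Integer scales 1..512 map to
analysis frequencies f = fc * fs / scale.  L1 normalization is used so a
unit-amplitude sinusoid produces a scale-independent ridge magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from skimage.transform import resize

from .types import SignalRecord

DEFAULT_TIME_BANDWIDTH = 0.234
DEFAULT_N_SCALES = 512
DEFAULT_CENTER_FREQ = 1.0  # cycles per sample at scale 1
REQUIRED_FS = 256.0


@dataclass
class Scalogram:
    magnitude: np.ndarray  # scales x samples, non-negative
    scales: np.ndarray
    fs: float
    wavelet: str = "morlet"
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH
    center_freq: float = DEFAULT_CENTER_FREQ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("scalogram magnitude must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        """Analysis frequency (Hz) of each scale row."""
        return self.center_freq * self.fs / self.scales


def scale_for_frequency(
    f0: float,
    fs: float = REQUIRED_FS,
    center_freq: float = DEFAULT_CENTER_FREQ,
) -> float:
    """Scale whose analysis frequency equals ``f0``."""
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    return center_freq * fs / f0


def cwt_scalogram(
    snippet: SignalRecord,
    n_scales: int = DEFAULT_N_SCALES,
    time_bandwidth: float = DEFAULT_TIME_BANDWIDTH,
    center_freq: float = DEFAULT_CENTER_FREQ,
) -> Scalogram:
    """|CWT| of a 256 Hz snippet over integer scales 1..n_scales."""
    if abs(snippet.fs - REQUIRED_FS) > 1e-9:
        raise ValueError(f"cwt_scalogram requires fs = {REQUIRED_FS} Hz, got {snippet.fs}")
    x = snippet.values
    if not np.all(np.isfinite(x)):
        raise ValueError("snippet contains non-finite values")
    n = x.size
    scales = np.arange(1, n_scales + 1, dtype=float)
    # zero padding covers the widest wavelet support (~4 sigma at max scale)
    sigma_max = scales[-1] * np.sqrt(time_bandwidth / 2.0)
    nfft = sfft.next_fast_len(n + int(4 * sigma_max) + 1)
    xhat = sfft.fft(x, nfft)
    w = 2 * np.pi * sfft.fftfreq(nfft)  # rad/sample
    wc = 2 * np.pi * center_freq
    mag = np.empty((n_scales, n))
    chunk = 64
    for i0 in range(0, n_scales, chunk):
        s = scales[i0 : i0 + chunk, None]
        psi = np.exp(-time_bandwidth * (s * w[None, :] - wc) ** 2 / 4.0)
        psi[:, w <= 0] = 0.0  # analytic wavelet
        coef = sfft.ifft(xhat[None, :] * psi, axis=1)[:, :n]
        mag[i0 : i0 + chunk] = np.abs(coef)
    coi_samples = scales * np.sqrt(2.0 * time_bandwidth)  # ~2 sigma of envelope
    return Scalogram(
        magnitude=mag,
        scales=scales,
        fs=snippet.fs,
        time_bandwidth=time_bandwidth,
        center_freq=center_freq,
        meta={"coi_samples": coi_samples, "t0": snippet.t0},
    )


def scalogram_to_image(s: Scalogram, size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Render to a size x size x 3 float image in [0, 1].

    Log-magnitude with a max-relative epsilon (so scaling the input magnitude
    by any constant yields the identical image), per-image min-max scaling,
    bilinear resize, channel replication.
    """
    m = s.magnitude
    if m.size == 0:
        raise ValueError("empty scalogram")
    peak = float(m.max())
    if peak <= 0:
        img = np.zeros(size)
    else:
        logm = np.log(m / peak + 1e-12)
        lo, hi = logm.min(), logm.max()
        norm = np.zeros_like(logm) if hi == lo else (logm - lo) / (hi - lo)
        img = resize(norm, size, order=1, mode="edge", anti_aliasing=False)
        rng = img.max() - img.min()
        img = (img - img.min()) / rng if rng > 0 else np.zeros(size)
    return np.repeat(img[:, :, None], 3, axis=2)
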