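"""Power spectral density, magnitude-squared coherence, band averaging.

Estimator: Welch averaged periodograms with Hann windows, 1 s windows
and 50% overlap by default, giving 1 Hz resolution — the granularity of
the analysis bands.  Band averages are arithmetic means over the grid
points falling inside the band, edges inclusive.

The canonical bands are the two spectral peaks this network exhibits,
Peak A (5-20 Hz: theta/alpha/low beta) and Peak B (25-45 Hz: high
beta/low gamma), plus an "overall" band: 5-50 Hz for power and
coherence, 0-50 Hz for GC spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .preprocess import Segment

__all__ = [
    "Band",
    "Spectrum",
    "CoherenceSpectra",
    "welch_psd",
    "coherence",
    "band_mean",
    "GC_BANDS",
    "POWER_BANDS",
]


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")


PEAK_A = Band("peakA", 5.0, 20.0)
PEAK_B = Band("peakB", 25.0, 45.0)

#: bands for GC spectra (overall = 0-50 Hz)
GC_BANDS = (Band("overall", 0.0, 50.0), PEAK_A, PEAK_B)

#: bands for power and coherence (overall = 5-50 Hz)
POWER_BANDS = (Band("overall", 5.0, 50.0), PEAK_A, PEAK_B)


@dataclass
class Spectrum:
    """Per-channel power spectral density over a uniform frequency grid.

    values : (n_channels, n_freqs), units of input^2 / Hz
    """

    freqs: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...]


@dataclass
class CoherenceSpectra:
    """Magnitude-squared coherence, (n, n, n_freqs), symmetric with unit
    diagonal, values in [0, 1]."""

    freqs: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...]


def _nperseg(seg: Segment, window_len: float) -> int:
    nps = int(round(window_len * seg.fs))
    if nps > seg.n_samples:
        raise ValueError(
            f"window of {window_len} s exceeds segment of "
            f"{seg.duration:.1f} s"
        )
    return nps


def welch_psd(seg: Segment, window_len: float = 1.0,
              overlap: float = 0.5) -> Spectrum:
    """Welch PSD per channel (Hann window, ``overlap`` fraction)."""
    nps = _nperseg(seg, window_len)
    freqs, pxx = scipy.signal.welch(
        seg.data, fs=seg.fs, window="hann", nperseg=nps,
        noverlap=int(nps * overlap), axis=0, detrend="constant",
    )
    return Spectrum(freqs=freqs, values=pxx.T, channels=seg.channels)


def coherence(seg: Segment, window_len: float = 1.0,
              overlap: float = 0.5) -> CoherenceSpectra:
    """Magnitude-squared coherence |S_xy|^2 / (S_xx S_yy) for every
    channel pair.

    Raises on a single averaging window (coherence is then identically
    one) and warns below 8 windows (estimates are upward biased by
    roughly 1/#windows).
    """
    nps = _nperseg(seg, window_len)
    nov = int(nps * overlap)
    step = nps - nov
    n_windows = 1 + (seg.n_samples - nps) // step if seg.n_samples >= nps else 0
    if n_windows < 2:
        raise ValueError(
            "coherence needs at least 2 averaging windows; with one "
            "window it is identically 1"
        )
    if n_windows < 8:
        warnings.warn(
            f"only {n_windows} averaging windows; coherence estimates are "
            "upward-biased"
        )
    freqs, sxx = scipy.signal.welch(
        seg.data, fs=seg.fs, window="hann", nperseg=nps, noverlap=nov,
        axis=0, detrend="constant",
    )
    n = len(seg.channels)
    out = np.ones((n, n, freqs.size))
    for i in range(n):
        for j in range(i + 1, n):
            _, sxy = scipy.signal.csd(
                seg.data[:, i], seg.data[:, j], fs=seg.fs, window="hann",
                nperseg=nps, noverlap=nov, detrend="constant",
            )
            c = np.abs(sxy) ** 2 / (sxx[:, i] * sxx[:, j])
            out[i, j] = out[j, i] = np.clip(c, 0.0, 1.0)
    return CoherenceSpectra(freqs=freqs, values=out, channels=seg.channels)


def band_mean(freqs: np.ndarray, values: np.ndarray, band: Band,
              axis: int = -1) -> np.ndarray:
    """Arithmetic mean of ``values`` over grid points with
    ``band.lo <= f <= band.hi`` (edges inclusive).

    Accepts a Spectrum / CoherenceSpectra in place of ``values`` when
    called with the object's own grid; here the array form keeps the
    function reusable for GC spectra too.
    """
    freqs = np.asarray(freqs)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not mask.any():
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) does not overlap "
            "the frequency grid"
        )
    values = np.asarray(values, dtype=float)
    return np.take(values, np.flatnonzero(mask), axis=axis).mean(axis=axis)
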