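"""Deterministic LFP signal conditioning and segmentation.

The conditioning chain, applied in this order, is: band-pass (1-150 Hz
Butterworth, second order, two-pass), notch at the line frequency and
its harmonics (60/120/240 Hz; notches at or above the Nyquist rate are
skipped), downsampling to 400 Hz behind an anti-aliasing low-pass at
45% of the target rate, splitting into consecutive non-overlapping
segments (300 s for GC, 30 s for power/coherence), and per-segment,
per-channel z-scoring before model estimation.

All filters are zero-phase (forward-backward application), so filtered
features stay aligned in time with the raw signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import scipy.signal

__all__ = [
    "Recording",
    "Segment",
    "bandpass",
    "notch",
    "resample",
    "split_segments",
    "normalize",
    "MONTAGE",
    "STATES",
]

#: canonical channel order for the 5-node cortico-subthalamic montage
MONTAGE = ("L-PMC", "L-M1", "R-PMC", "R-M1", "L-STN")

#: ordered disease states
STATES = ("naive", "mild", "moderate")


@dataclass
class Recording:
    """One continuous multichannel LFP session.

    data : (samples, channels) float array, arbitrary units
    fs : sampling rate, Hz
    channels : ordered channel labels
    state : disease-state label
    session_id : unique session identifier
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    state: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be (samples, channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count does not match label count")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment(Recording):
    """A fixed-duration non-overlapping window of a recording, used as
    one analysis trial."""

    parent_session: str = ""
    index: int = 0

    @property
    def trial_id(self) -> str:
        return f"{self.parent_session}/{self.index}"


def _apply(rec: Recording, data: np.ndarray, **changes) -> Recording:
    return replace(rec, data=data, **changes)


def bandpass(rec: Recording, lo: float = 1.0, hi: float = 150.0,
             order: int = 2) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    ``order`` is the order of the underlying low/high-pass prototype
    (a second-order band-pass as conventionally reported); two passes
    square the magnitude response.
    """
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(
            f"band ({lo}, {hi}) Hz must satisfy 0 < lo < hi < Nyquist ({nyq})"
        )
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass",
                              fs=rec.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, rec.data, axis=0)
    return _apply(rec, out)


def notch(rec: Recording, freqs=(60.0, 120.0, 240.0),
          q: float = 35.0) -> Recording:
    """Zero-phase IIR band-stop at each frequency (quality factor ``q``).

    Frequencies at or above the Nyquist rate (e.g. a 240 Hz notch on a
    400 Hz recording) are skipped with a warning rather than an error,
    since harmonics can fall out of band after downsampling.
    """
    freqs = list(freqs)
    if not freqs:
        warnings.warn("empty notch frequency list; returning input unchanged")
        return _apply(rec, rec.data.copy())
    nyq = rec.fs / 2.0
    out = rec.data
    for f in freqs:
        if f >= nyq:
            warnings.warn(
                f"notch at {f} Hz skipped: at or above Nyquist ({nyq} Hz)"
            )
            continue
        b, a = scipy.signal.iirnotch(f, Q=q, fs=rec.fs)
        out = scipy.signal.filtfilt(b, a, out, axis=0)
    return _apply(rec, out)


def resample(rec: Recording, target_fs: float = 400.0,
             aa_fraction: float = 0.45) -> Recording:
    """Polyphase rate conversion behind an anti-aliasing low-pass.

    The anti-aliasing FIR cuts off at ``aa_fraction * target_fs``
    (default 45% of the target rate, matching the acquisition
    convention), applied as the polyphase filter itself so the output is
    delay-compensated.  Non-integer ratios are handled by rational
    approximation of target_fs / fs.
    """
    if target_fs >= rec.fs:
        raise ValueError(
            f"target_fs ({target_fs}) must be below the current rate ({rec.fs})"
        )
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    fs_up = rec.fs * up
    cutoff = aa_fraction * target_fs
    # transition band of 10% of the target Nyquist keeps the stopband
    # (first aliased frequency) well attenuated
    width = 0.1 * (target_fs / 2.0)
    numtaps, beta = scipy.signal.kaiserord(80.0, width / (fs_up / 2.0))
    numtaps |= 1  # odd length -> exactly linear phase, integer delay
    h = scipy.signal.firwin(numtaps, cutoff, window=("kaiser", beta),
                            fs=fs_up)
    out = scipy.signal.resample_poly(rec.data, up, down, axis=0,
                                     window=h * up)
    return _apply(rec, out, fs=float(target_fs))


def split_segments(rec: Recording, duration: float) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping segments of
    ``duration`` seconds, starting at sample 0; the trailing remainder
    shorter than one segment is discarded."""
    seg_len = int(round(duration * rec.fs))
    if seg_len < 1:
        raise ValueError("segment duration must cover at least one sample")
    k = rec.n_samples // seg_len
    if k == 0:
        warnings.warn(
            f"recording {rec.session_id!r} shorter than one {duration} s "
            "segment; returning no segments"
        )
        return []
    return [
        Segment(
            data=rec.data[i * seg_len:(i + 1) * seg_len].copy(),
            fs=rec.fs,
            channels=rec.channels,
            state=rec.state,
            session_id=rec.session_id,
            parent_session=rec.session_id,
            index=i,
        )
        for i in range(k)
    ]


def normalize(seg: Segment) -> Segment:
    """Per-channel z-score (mean 0, unit variance) within the segment.

    GC is invariant to channel scale, but normalization removes
    amplitude bias from the model-order selection and keeps the OLS
    problem well conditioned.
    """
    mu = seg.data.mean(axis=0)
    sd = seg.data.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd < 1e-10 * np.maximum(1.0, np.abs(mu)))
    if bad.size:
        names = ", ".join(seg.channels[i] for i in bad)
        raise ValueError(f"zero-variance channel(s): {names}")
    out = (seg.data - mu) / sd
    return replace(seg, data=out)
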