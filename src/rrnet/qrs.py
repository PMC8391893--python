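"""QRS detection and RR-interval extraction from sampled ECG.

The detector is the classic energy pipeline: band-pass (5-15 Hz) ->
differentiate -> square -> moving-window integrate -> adaptive threshold
with a 0.2 s refractory period, followed by R-peak refinement on the
band-passed signal. Detection errors are deliberately left in the RR
streams; a rhythm classifier has to be robust to them, so no post-hoc
interval filtering is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import RRBlock

__all__ = ["ECGRecord", "detect_beats", "rr_from_beats", "compression_ratio",
           "block_from_record"]

REFRACTORY_S = 0.2


@dataclass(frozen=True, eq=False)
class ECGRecord:
    """A multi-lead sampled ECG with an optional rhythm label."""

    patient_id: str
    fs: float
    samples: np.ndarray  # (channels, time)
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if samples.shape[0] < 1 or samples.ndim != 2:
            raise ValueError("need at least one channel of equal-length samples")


def detect_beats(record: ECGRecord, channel: int = 0) -> np.ndarray:
    """Detect R-peak sample indices on one channel.

    Returns a strictly increasing index array; successive beats are at least
    0.2 s apart. A flat (zero-variance) trace yields an empty result with a
    warning rather than an exception.
    """
    x = record.samples[channel].astype(float)
    fs = record.fs
    if x.size < 2 * fs:
        raise ValueError("record must hold at least 2 s of samples")
    if np.ptp(x) == 0:
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return np.empty(0, dtype=int)

    # zero-pad so boundary beats are not distorted by the filter transient
    pad = int(round(0.5 * fs))
    xpad = np.concatenate([np.zeros(pad), x, np.zeros(pad)])

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bp = sps.filtfilt(b, a, xpad)
    energy = np.gradient(bp) ** 2
    win = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    dist = max(int(round(REFRACTORY_S * fs)), 1)
    # adaptive threshold: a fraction of a robust peak-height estimate
    cand, _ = sps.find_peaks(integ, distance=dist)
    if cand.size == 0:
        return np.empty(0, dtype=int)
    level = 0.2 * np.percentile(integ[cand], 95)
    peaks, _ = sps.find_peaks(integ, distance=dist, height=level)

    # refine each detection to the local R extremum of the raw trace
    half = max(int(round(0.10 * fs)), 1)
    xr = np.abs(x - np.median(x))
    refined = []
    for p in peaks:
        c = min(max(p - pad, 0), x.size - 1)
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        refined.append(lo + int(np.argmax(xr[lo:hi])))
    refined = np.unique(refined)
    # re-impose the refractory constraint after refinement
    out: list[int] = []
    for r in refined:
        if not out or r - out[-1] >= dist:
            out.append(int(r))
    return np.asarray(out, dtype=int)


def rr_from_beats(indices: np.ndarray, fs: float) -> np.ndarray:
    """Convert beat sample indices to RR intervals in seconds.

    ``n`` beats yield ``n - 1`` intervals; fewer than two beats yield an
    empty sequence.
    """
    indices = np.asarray(indices)
    if not fs > 0:
        raise ValueError("fs must be positive")
    if indices.size >= 2 and np.any(np.diff(indices) <= 0):
        raise ValueError("beat indices must be strictly increasing")
    if indices.size < 2:
        return np.empty(0)
    return np.diff(indices) / fs


def compression_ratio(n_samples: int, n_rr: int) -> float:
    """Data-reduction ratio of the QRS step: raw samples per RR interval."""
    if n_rr == 0:
        raise ZeroDivisionError("undefined compression ratio: no RR intervals")
    return n_samples / n_rr


def block_from_record(record: ECGRecord, channel: int = 0) -> RRBlock | None:
    """Extract one labelled RR block from a record; None if < 2 beats found."""
    beats = detect_beats(record, channel=channel)
    rr = rr_from_beats(beats, record.fs)
    if rr.size == 0:
        return None
    duration = record.samples.shape[1] / record.fs
    return RRBlock(patient_id=record.patient_id, label=record.label or "unknown",
                   rr=rr, duration=duration)
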