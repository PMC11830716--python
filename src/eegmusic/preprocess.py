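"""Trial alignment, slicing and filtering.

Pipeline order: align the recording to the stimulus markers, downsample
1000 -> 256 Hz, remove the channel mean, notch out 50 Hz mains, segment
into non-overlapping 5-s slices, and band-pass each slice into the five
EEG rhythms with zero-phase Butterworth filters.

Trial time is seconds from stimulus onset; windows are half-open
[start, end).  A slice is labelled ``speaking`` iff its window lies
inside the read-aloud interval (40-60 s by default).  The analysis
windows used downstream are 30-40 s (quiet) and 40-50 s (speaking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import BANDS, CHANNELS, FS_ANALYSIS
from .synth import RawTrial


class AlignmentError(ValueError):
    pass


@dataclass
class SliceRecord:
    """One 5-s window of a preprocessed trial."""

    subject_id: str
    emotion: str
    state: str  # "quiet" | "speaking"
    window: tuple[float, float]  # trial time, [start, end)
    signal: np.ndarray  # channels x samples at fs
    fs: int = FS_ANALYSIS
    channels: tuple[str, ...] = CHANNELS


#: BandSet: mapping band name -> filtered signal of the same shape
BandSet = dict


def align_trial(trial: RawTrial) -> RawTrial:
    """Trim the recording to exactly [stim_start, stim_end)."""
    ts = trial.timestamps
    if trial.stim_start < ts[0] - 1e-9 or trial.stim_end > ts[-1] + 1.0 / trial.fs:
        raise AlignmentError("stimulus markers outside the recorded span")
    i0 = int(np.searchsorted(ts, trial.stim_start - 1e-9, side="left"))
    n_keep = round((trial.stim_end - trial.stim_start) * trial.fs)
    if i0 + n_keep > trial.signal.shape[1]:
        raise AlignmentError("recording too short for the stimulus span")
    out = RawTrial(
        subject_id=trial.subject_id,
        emotion=trial.emotion,
        signal=trial.signal[:, i0:i0 + n_keep],
        timestamps=ts[i0:i0 + n_keep],
        stim_start=trial.stim_start,
        stim_end=trial.stim_end,
        fs=trial.fs,
        channels=trial.channels,
    )
    return out


def downsample(signal: np.ndarray, fs_in: int = 1000, fs_out: int = 256) -> np.ndarray:
    """Polyphase resampling with built-in anti-aliasing low-pass."""
    if fs_out >= fs_in:
        raise ValueError("fs_out must be below fs_in")
    from math import gcd

    g = gcd(fs_in, fs_out)
    return sps.resample_poly(np.asarray(signal, dtype=float),
                             fs_out // g, fs_in // g, axis=-1)


def center(signal: np.ndarray) -> np.ndarray:
    """Remove the mean of each channel."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    return signal - signal.mean(axis=-1, keepdims=True)


def notch_50hz(signal: np.ndarray, fs: int = FS_ANALYSIS, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at 50 Hz (quality factor 30)."""
    if fs <= 100:
        raise ValueError("fs must exceed 100 Hz to notch 50 Hz")
    b, a = sps.iirnotch(50.0, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=float), axis=-1)


def band_decompose(signal: np.ndarray, fs: int = FS_ANALYSIS, order: int = 4) -> BandSet:
    """Butterworth band-pass (zero-phase, order 4) into the five rhythms."""
    signal = np.asarray(signal, dtype=float)
    out: BandSet = {}
    for band, (lo, hi) in BANDS.items():
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out[band] = sps.sosfiltfilt(sos, signal, axis=-1)
    return out


def segment(signal: np.ndarray, fs: int, subject_id: str, emotion: str,
            window_s: float = 5.0,
            speaking_window: tuple[float, float] = (40.0, 60.0),
            channels: tuple[str, ...] = CHANNELS) -> list[SliceRecord]:
    """Cut an aligned, preprocessed trial into consecutive 5-s slices.

    Any remainder shorter than one window is truncated.  State is
    ``speaking`` iff the slice lies inside ``speaking_window``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_per = round(window_s * fs)
    n_slices = signal.shape[1] // n_per
    if n_slices == 0:
        raise ValueError("trial shorter than one window")
    lo, hi = speaking_window
    slices = []
    for k in range(n_slices):
        w0, w1 = k * window_s, (k + 1) * window_s
        state = "speaking" if (w0 >= lo and w1 <= hi) else "quiet"
        slices.append(
            SliceRecord(
                subject_id=subject_id,
                emotion=emotion,
                state=state,
                window=(w0, w1),
                signal=signal[:, k * n_per:(k + 1) * n_per],
                fs=fs,
                channels=channels,
            )
        )
    return slices


#: analysis windows per state: quiet 30-40 s, speaking 40-50 s
ANALYSIS_WINDOWS = {"quiet": ((30.0, 35.0), (35.0, 40.0)),
                    "speaking": ((40.0, 45.0), (45.0, 50.0))}


def analysis_slices(slices: list[SliceRecord]) -> list[SliceRecord]:
    """Keep only the slices inside the 30-40 s / 40-50 s analysis windows."""
    keep = {w for ws in ANALYSIS_WINDOWS.values() for w in ws}
    return [s for s in slices if s.window in keep]


def preprocess_trial(trial: RawTrial, fs_out: int = FS_ANALYSIS,
                     window_s: float = 5.0,
                     speaking_window: tuple[float, float] = (40.0, 60.0)
                     ) -> list[SliceRecord]:
    """Full preprocessing of one raw trial into 5-s slices at 256 Hz."""
    aligned = align_trial(trial)
    x = downsample(aligned.signal, aligned.fs, fs_out)
    x = center(x)
    x = notch_50hz(x, fs_out)
    return segment(x, fs_out, trial.subject_id, trial.emotion,
                   window_s=window_s, speaking_window=speaking_window,
                   channels=trial.channels)
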