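"""Dual-threshold speech endpoint detection.

Classic two-stage voice-activity detection on the 40-60 s read-aloud
audio: short-time energy frames seeded above a high threshold are
extended outward while energy stays above a low threshold, then further
extended while the zero-crossing rate exceeds its own threshold.
Thresholds are derived from the leading frames, assumed to contain no
speech.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FrameFeatures:
    """Per-frame short-time energy and zero-crossing rate."""

    energy: np.ndarray  # sum of squared windowed samples per frame
    zcr: np.ndarray  # sign changes / frame length, in [0, 1]
    frame_s: float
    hop_s: float

    @property
    def times(self) -> np.ndarray:
        """Frame centre times in seconds."""
        return np.arange(len(self.energy)) * self.hop_s + self.frame_s / 2


@dataclass
class SpeechSegment:
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class VadConfig:
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    #: leading seconds assumed non-speech, used to set thresholds
    noise_head_s: float = 0.5
    #: T_low = noise mean + k_low * SD of noise energy
    k_low: float = 3.0
    #: T_high = high_ratio * T_low
    high_ratio: float = 5.0
    #: ZCR threshold = noise ZCR mean + k_zcr * SD
    k_zcr: float = 2.0
    use_zcr: bool = True


def frame_analyze(audio: np.ndarray, fs: int, frame_ms: float = 25.0,
                  hop_ms: float = 10.0) -> FrameFeatures:
    """Short-time energy (Hamming-windowed) and ZCR per frame."""
    audio = np.asarray(audio, dtype=float)
    n_frame = round(frame_ms * fs / 1000)
    n_hop = round(hop_ms * fs / 1000)
    if audio.size < n_frame:
        raise ValueError("audio shorter than one frame")
    n_frames = (audio.size - n_frame) // n_hop + 1
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = audio[idx]
    win = np.hamming(n_frame)
    energy = np.sum((frames * win) ** 2, axis=1)
    signs = np.signbit(frames)
    zcr = np.sum(signs[:, 1:] != signs[:, :-1], axis=1) / n_frame
    return FrameFeatures(energy=energy, zcr=zcr,
                         frame_s=n_frame / fs, hop_s=n_hop / fs)


def derive_thresholds(features: FrameFeatures, config: VadConfig) -> dict:
    """Energy/ZCR thresholds from the leading noise-only frames."""
    n_head = max(2, int(config.noise_head_s / features.hop_s))
    e = features.energy[:n_head]
    z = features.zcr[:n_head]
    t_low = e.mean() + config.k_low * e.std()
    return {
        "t_low": t_low,
        "t_high": config.high_ratio * t_low,
        "t_zcr": z.mean() + config.k_zcr * z.std(),
    }


def detect_endpoints(features: FrameFeatures, thresholds: dict | None = None,
                     config: VadConfig | None = None) -> SpeechSegment | None:
    """Earliest dual-threshold speech segment, or None if no seed frame.

    A segment is seeded at the first frame with energy > t_high,
    extended outward while energy > t_low, then extended while the ZCR
    exceeds its threshold (skipped when ``config.use_zcr`` is False).
    """
    config = config or VadConfig()
    if thresholds is None:
        thresholds = derive_thresholds(features, config)
    t_low, t_high = thresholds["t_low"], thresholds["t_high"]
    if t_high <= t_low:
        raise ValueError("t_high must exceed t_low")
    e = features.energy
    seeds = np.flatnonzero(e > t_high)
    if seeds.size == 0:
        return None
    seed = int(seeds[0])
    lo = seed
    while lo > 0 and e[lo - 1] > t_low:
        lo -= 1
    hi = seed
    while hi < len(e) - 1 and e[hi + 1] > t_low:
        hi += 1
    if config.use_zcr:
        t_zcr = thresholds["t_zcr"]
        z = features.zcr
        while lo > 0 and z[lo - 1] > t_zcr:
            lo -= 1
        while hi < len(e) - 1 and z[hi + 1] > t_zcr:
            hi += 1
    onset = lo * features.hop_s
    offset = hi * features.hop_s + features.frame_s
    return SpeechSegment(onset_s=onset, offset_s=offset)


def detect_speech(audio: np.ndarray, fs: int,
                  config: VadConfig | None = None) -> SpeechSegment | None:
    """Convenience: frame analysis + threshold derivation + detection."""
    config = config or VadConfig()
    feats = frame_analyze(audio, fs, config.frame_ms, config.hop_ms)
    return detect_endpoints(feats, None, config)


def duration_summary(segments: list[SpeechSegment], bin_s: float = 1.0) -> dict:
    """Histogram tables of onsets, offsets and durations.

    Returns a dict with one DataFrame per quantity (columns
    ``bin_left``, ``bin_right``, ``count``) plus the modal bin of each.
    """
    if not segments:
        raise ValueError("no segments to summarize")
    out: dict = {}
    for name, values in (
        ("onset", np.array([s.onset_s for s in segments])),
        ("offset", np.array([s.offset_s for s in segments])),
        ("duration", np.array([s.duration_s for s in segments])),
    ):
        lo = np.floor(values.min() / bin_s) * bin_s
        hi = np.ceil(values.max() / bin_s) * bin_s
        edges = np.arange(lo, hi + bin_s, bin_s)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_s])
        counts, edges = np.histogram(values, bins=edges)
        table = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
        mode = int(np.argmax(counts))
        out[name] = table
        out[f"{name}_modal_range"] = (float(edges[mode]), float(edges[mode + 1]))
    return out


def vad_table(clips: dict[str, tuple[np.ndarray, int]],
              config: VadConfig | None = None) -> pd.DataFrame:
    """Run detection over named clips; one row per clip."""
    rows = []
    for clip_id, (audio, fs) in clips.items():
        seg = detect_speech(audio, fs, config)
        rows.append(
            {
                "clip_id": clip_id,
                "onset_s": seg.onset_s if seg else np.nan,
                "offset_s": seg.offset_s if seg else np.nan,
                "duration_s": seg.duration_s if seg else np.nan,
            }
        )
    return pd.DataFrame(rows)
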