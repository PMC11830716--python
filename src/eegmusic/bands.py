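"""Frequency-band and montage conventions used throughout the package.

The five conventional EEG rhythms are taken with the corner frequencies
used in the study design: delta 0.5-4 Hz, theta 4-8 Hz, alpha 8-14 Hz,
beta 14-30 Hz, gamma 30-44 Hz.  Recording montage is five frontal 10-20
sites: F7, Fp1, Fz, Fp2, F8.
"""

from __future__ import annotations

# ordered: low to high frequency
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 44.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

CHANNELS: tuple[str, ...] = ("F7", "Fp1", "Fz", "Fp2", "F8")

EMOTIONS: tuple[str, ...] = (
    "fear",
    "sadness",
    "anger",
    "calmness",
    "happiness",
    "tension",
)

#: sampling rate of the raw acquisition (Hz)
FS_RAW = 1000
#: analysis sampling rate after downsampling (Hz)
FS_ANALYSIS = 256
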