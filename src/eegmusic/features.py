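"""Per-slice feature families: statistics, power spectra, wavelet packets.

Three families are extracted per 5-s slice:

* ``stats`` — mean, variance, SD, skewness, kurtosis (bias-corrected)
  and average power of each band-filtered signal, per channel: 5
  channels x 5 bands x 6 statistics = 150 columns.
* ``psd`` — log-periodogram of the broadband slice averaged in 2-Hz
  bins over 0.5-44 Hz, plus total log-power per band, per channel.
* ``wavelet`` — full db4 wavelet-packet tree to level 8 (0.5 Hz leaf
  bins at 256 Hz); leaves are re-ranked from natural into frequency
  order, mapped onto the five bands, and summarised as per-leaf log
  energies (``summary="coeffs"`` keeps raw coefficient concatenation).

The packet recursion convolves each node with the analysis pair
(h, g) and downsamples by two, with periodic boundary handling so the
transform is orthonormal and node energies sum to the signal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats as sstats

from .bands import BANDS, FS_ANALYSIS
from .preprocess import SliceRecord, band_decompose

STAT_NAMES = ("mean", "variance", "sd", "skewness", "kurtosis", "avg_power")


def stat_features(x: np.ndarray) -> dict[str, float]:
    """Six summary statistics of one signal.

    Variance/SD use the N-1 denominator; skewness and kurtosis are the
    bias-corrected sample versions (kurtosis is excess kurtosis);
    average power is the mean squared sample.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 3:
        raise ValueError("need at least 4 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("skewness/kurtosis undefined for a constant signal")
    return {
        "mean": float(np.mean(x)),
        "variance": float(np.var(x, ddof=1)),
        "sd": sd,
        "skewness": float(sstats.skew(x, bias=False)),
        "kurtosis": float(sstats.kurtosis(x, bias=False)),
        "avg_power": float(np.mean(x**2)),
    }


def psd(x: np.ndarray, one_sided: bool = False):
    """Periodogram P_k = |X_k|^2 / N from the N-point DFT.

    With this normalisation Parseval's identity reads
    ``sum_k P_k = sum_n x_n**2`` (two-sided form).  When ``one_sided``,
    returns (freq_bins, P) over the non-negative frequencies of the
    two-sided density (not folded).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    X = np.fft.fft(x)
    P = np.abs(X) ** 2 / n
    if one_sided:
        m = n // 2 + 1
        return np.arange(m), P[:m]
    return P


@dataclass
class WaveletPacketTree:
    """Full wavelet-packet analysis tree of one signal."""

    wavelet: str
    level: int
    h: np.ndarray  # low-pass analysis filter
    g: np.ndarray  # high-pass analysis filter
    #: (level, natural index) -> coefficient array
    nodes: dict[tuple[int, int], np.ndarray]

    def leaves_natural(self) -> list[np.ndarray]:
        return [self.nodes[(self.level, i)] for i in range(2**self.level)]

    def leaves_frequency(self) -> list[np.ndarray]:
        """Leaves re-ranked so index increases with centre frequency."""
        return [self.nodes[(self.level, natural_index(f, self.level))]
                for f in range(2**self.level)]


def natural_index(freq_rank: int, level: int) -> int:
    """Natural (tree-path) index of the leaf with given frequency rank.

    The high-pass branch mirrors the spectrum of its children, so
    natural order interleaves frequencies; the frequency-ordered leaf f
    sits at natural position gray(f) = f ^ (f >> 1).
    """
    del level  # rank/index relation is level-independent
    return freq_rank ^ (freq_rank >> 1)


def _analysis_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """y[n] = sum_k filt[k] * x[(2n - k) mod N]; periodic, N even."""
    n = x.size
    conv = np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(filt, n), n)
    return conv[::2]


def wp_decompose(x: np.ndarray, level: int = 8, wavelet: str = "db4") -> WaveletPacketTree:
    """Full wavelet-packet decomposition with periodic boundaries."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n % (2**level) != 0 or n < 2**level * 2:
        raise ValueError(
            f"signal length {n} not decomposable to level {level} "
            "(must be divisible by 2**level with >= 2 samples per leaf)"
        )
    w = pywt.Wavelet(wavelet)
    h = np.asarray(w.dec_lo, dtype=float)
    g = np.asarray(w.dec_hi, dtype=float)
    if n // 2 ** (level - 1) < h.size:
        # deepest convolution would wrap the filter more than once past
        # what the FFT padding supports
        if n // 2 ** (level - 1) < h.size // 2:
            raise ValueError("signal too short for the requested level")
    nodes: dict[tuple[int, int], np.ndarray] = {(0, 0): x}
    for lvl in range(1, level + 1):
        for i in range(2 ** (lvl - 1)):
            parent = nodes[(lvl - 1, i)]
            nodes[(lvl, 2 * i)] = _analysis_step(parent, h)
            nodes[(lvl, 2 * i + 1)] = _analysis_step(parent, g)
    return WaveletPacketTree(wavelet=wavelet, level=level, h=h, g=g, nodes=nodes)


def band_leaf_ranks(level: int = 8, fs: int = FS_ANALYSIS,
                    bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, list[int]]:
    """Frequency-ordered leaf ranks whose nominal bin lies inside each band.

    Leaf f nominally covers [f*w, (f+1)*w) Hz with w = (fs/2) / 2**level
    (0.5 Hz at level 8, 256 Hz).
    """
    w = (fs / 2) / 2**level
    out = {}
    for band, (lo, hi) in bands.items():
        out[band] = [f for f in range(2**level)
                     if f * w >= lo - 1e-9 and (f + 1) * w <= hi + 1e-9]
    return out


def wp_band_features(tree: WaveletPacketTree, fs: int = FS_ANALYSIS,
                     summary: str = "energy") -> dict[str, np.ndarray]:
    """Band-tagged features from the frequency-ordered level-L leaves.

    ``summary="energy"`` (default): log mean-square coefficient per
    leaf; ``summary="coeffs"``: raw concatenated leaf coefficients.
    """
    ranks = band_leaf_ranks(tree.level, fs)
    leaves = tree.leaves_frequency()
    out = {}
    for band, idxs in ranks.items():
        if summary == "coeffs":
            out[band] = np.concatenate([leaves[f] for f in idxs])
        elif summary == "energy":
            out[band] = np.array(
                [np.log(np.mean(leaves[f] ** 2) + 1e-12) for f in idxs]
            )
        else:
            raise ValueError(f"unknown summary {summary!r}")
    return out


# ---------------------------------------------------------------------------
# family assembly

#: 2-Hz periodogram bin edges over the retained 0.5-44 Hz range
PSD_BIN_EDGES = np.array([0.5] + list(range(2, 46, 2)), dtype=float)


@dataclass
class FeatureMatrix:
    """Design matrix of one feature family with labels and row metadata."""

    family: str
    X: np.ndarray  # slices x features
    y: np.ndarray  # emotion labels
    meta: pd.DataFrame  # subject, state, window_start per row
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.meta)):
            raise ValueError("X, y and meta must have equal row counts")
        if np.isnan(np.asarray(self.X, dtype=float)).any():
            raise ValueError("feature matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "emotion", self.y)
        for col in reversed(self.meta.columns):
            df.insert(0, col, self.meta[col].to_numpy())
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, family: str) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("subject_id", "state", "window_start") if c in df]
        names = [c for c in df.columns if c not in meta_cols + ["emotion"]]
        return cls(family=family, X=df[names].to_numpy(dtype=float),
                   y=df["emotion"].to_numpy(), meta=df[meta_cols].copy(),
                   feature_names=names)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.family, self.X[mask], self.y[mask],
                             self.meta.iloc[mask].reset_index(drop=True),
                             self.feature_names)


def _stats_row(slc: SliceRecord) -> tuple[list[float], list[str]]:
    vals, names = [], []
    for ci, ch in enumerate(slc.channels):
        bandset = band_decompose(slc.signal[ci], slc.fs)
        for band, sig in bandset.items():
            feats = stat_features(sig)
            for stat in STAT_NAMES:
                vals.append(feats[stat])
                names.append(f"{ch}:{band}:{stat}")
    return vals, names


def _psd_row(slc: SliceRecord) -> tuple[list[float], list[str]]:
    vals, names = [], []
    n = slc.signal.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / slc.fs)
    for ci, ch in enumerate(slc.channels):
        spec = np.abs(np.fft.rfft(slc.signal[ci])) ** 2 / n
        for lo, hi in zip(PSD_BIN_EDGES[:-1], PSD_BIN_EDGES[1:]):
            m = (freqs >= lo) & (freqs < hi)
            vals.append(float(np.log(spec[m].mean() + 1e-12)))
            names.append(f"{ch}:psd:{lo:g}-{hi:g}")
        for band, (lo, hi) in BANDS.items():
            m = (freqs >= lo) & (freqs < hi)
            vals.append(float(np.log(spec[m].sum() + 1e-12)))
            names.append(f"{ch}:{band}:logpower")
    return vals, names


def _wavelet_row(slc: SliceRecord, level: int, summary: str
                 ) -> tuple[list[float], list[str]]:
    vals, names = [], []
    ranks = band_leaf_ranks(level, slc.fs)
    for ci, ch in enumerate(slc.channels):
        tree = wp_decompose(slc.signal[ci], level=level)
        feats = wp_band_features(tree, slc.fs, summary=summary)
        for band, arr in feats.items():
            for j, v in enumerate(arr):
                tag = (f"leaf{ranks[band][j]}" if summary == "energy"
                       else f"c{j}")
                vals.append(float(v))
                names.append(f"{ch}:wp:{band}:{tag}")
    return vals, names


FAMILIES = ("stats", "psd", "wavelet")


def extract_all(slices: list[SliceRecord], families=FAMILIES, level: int = 8,
                wavelet_summary: str = "energy") -> dict[str, FeatureMatrix]:
    """One pass over slices computing every requested family."""
    if not slices:
        raise ValueError("no slices to assemble")
    order = sorted(range(len(slices)),
                   key=lambda i: (slices[i].subject_id, slices[i].emotion,
                                  slices[i].window))
    rows: dict[str, list[list[float]]] = {f: [] for f in families}
    names: dict[str, list[str]] = {}
    meta_rows, labels = [], []
    expected_n = None
    for i in order:
        slc = slices[i]
        n = slc.signal.shape[1]
        if expected_n is None:
            expected_n = n
        elif n != expected_n:
            raise ValueError("inconsistent slice lengths")
        for fam in families:
            if fam == "stats":
                vals, nm = _stats_row(slc)
            elif fam == "psd":
                vals, nm = _psd_row(slc)
            elif fam == "wavelet":
                vals, nm = _wavelet_row(slc, level, wavelet_summary)
            else:
                raise ValueError(f"unknown family {fam!r}")
            rows[fam].append(vals)
            names[fam] = nm
        labels.append(slc.emotion)
        meta_rows.append({"subject_id": slc.subject_id, "state": slc.state,
                          "window_start": slc.window[0]})
    meta = pd.DataFrame(meta_rows)
    return {
        fam: FeatureMatrix(family=fam, X=np.asarray(rows[fam]),
                           y=np.asarray(labels), meta=meta.copy(),
                           feature_names=names[fam])
        for fam in families
    }


def assemble(slices: list[SliceRecord], family: str, level: int = 8,
             wavelet_summary: str = "energy") -> FeatureMatrix:
    """Feature matrix of one family; rows sorted by (subject, emotion, window)."""
    return extract_all(slices, (family,), level, wavelet_summary)[family]
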