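"""Band x channel significance analysis of emotion effects.

For each (band, channel, state) the standard deviation of the
band-filtered signal in each 5-s analysis window is one observation;
a one-way fixed-effects ANOVA across the six emotions tests for any
emotion effect, Bonferroni correction (family size m = 50: 5 bands x
5 channels x 2 states) controls the family-wise error, and two-sided
independent-samples t-tests give the 15 pairwise emotion contrasts,
rendered as a 6x6 significance mask per cell of the 5x5 band/channel
grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bands import BAND_NAMES, CHANNELS, EMOTIONS
from .preprocess import SliceRecord, band_decompose

#: default Bonferroni family: 5 bands x 5 channels x 2 states
DEFAULT_FAMILY_SIZE = 50

STATES = ("speaking", "quiet")


def band_sd_observations(slices: list[SliceRecord]) -> pd.DataFrame:
    """One band-SD observation per (slice, channel, band).

    SD uses the N-1 denominator.  Each 5-s window contributes its own
    observation (windows are not pooled within a state).
    """
    rows = []
    for slc in slices:
        for ci, ch in enumerate(slc.channels):
            bands = band_decompose(slc.signal[ci], slc.fs)
            for band, sig in bands.items():
                rows.append(
                    {
                        "subject_id": slc.subject_id,
                        "emotion": slc.emotion,
                        "state": slc.state,
                        "channel": ch,
                        "band": band,
                        "window_start": slc.window[0],
                        "sd": float(np.std(sig, ddof=1)),
                    }
                )
    return pd.DataFrame(rows)


def _groups(obs: pd.DataFrame, band: str, channel: str, state: str):
    sub = obs[(obs["band"] == band) & (obs["channel"] == channel)
              & (obs["state"] == state)]
    if sub.empty:
        raise ValueError(f"no observations for {band}/{channel}/{state}")
    groups = [sub.loc[sub["emotion"] == emo, "sd"].to_numpy()
              for emo in EMOTIONS if (sub["emotion"] == emo).any()]
    if len(groups) < 2:
        raise ValueError("need at least 2 emotion groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every emotion group needs >= 2 observations")
    return groups


def anova_emotions(obs: pd.DataFrame, band: str, channel: str, state: str) -> dict:
    """One-way fixed-effects ANOVA of band SD across the emotions."""
    groups = _groups(obs, band, channel, state)
    F, p = sstats.f_oneway(*groups)
    return {"F": float(F), "p": float(p)}


def bonferroni(p_values, m: int = DEFAULT_FAMILY_SIZE):
    """min(1, m * p); monotone, capped family-wise correction."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    out = np.minimum(1.0, m * p)
    return float(out) if np.isscalar(p_values) else out


def pairwise_ttests(obs: pd.DataFrame, band: str, channel: str, state: str,
                    alpha: float = 0.05, equal_var: bool = True):
    """6x6 p-value matrix and binary significance mask at ``alpha``.

    Student's pooled-variance t-test by default (Welch via
    ``equal_var=False``); a degenerate pooled variance falls back to
    Welch automatically.
    """
    groups = _groups(obs, band, channel, state)
    k = len(groups)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            if equal_var and (gi.var(ddof=1) + gj.var(ddof=1)) == 0:
                res = sstats.ttest_ind(gi, gj, equal_var=False)
            else:
                res = sstats.ttest_ind(gi, gj, equal_var=equal_var)
            p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
            pmat[i, j] = pmat[j, i] = p
    labels = list(EMOTIONS[:k])
    pdf = pd.DataFrame(pmat, index=labels, columns=labels)
    mask = (pdf < alpha).astype(int)
    np.fill_diagonal(mask.values, 0)
    return pdf, mask


def type1_calibration(n_reps: int = 500, n_per_group: int = 12,
                      n_groups: int = 6, n_samples: int = 1280,
                      band: str = "alpha", fs: int = 256,
                      alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical ANOVA false-positive rate under the null generator.

    Each replicate draws ``n_groups`` emotion groups of band-SD
    observations with *no* emotion effect (every observation is the
    sample SD of freshly generated band-limited Gaussian noise) and
    tests them with :func:`anova_emotions`'s one-way ANOVA.  Returns
    the fraction of replicates with p < ``alpha``; a calibrated test
    sits near ``alpha``.
    """
    from scipy import signal as spsig

    from .bands import BANDS

    lo, hi = BANDS[band]
    sos = spsig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    rng = np.random.default_rng(seed)
    hits = 0
    n_obs = n_per_group * n_groups
    for _ in range(n_reps):
        noise = rng.standard_normal((n_obs, n_samples))
        sds = spsig.sosfiltfilt(sos, noise, axis=-1).std(axis=-1, ddof=1)
        groups = sds.reshape(n_groups, n_per_group)
        _, p = sstats.f_oneway(*groups)
        hits += p < alpha
    return hits / n_reps


def significance_table(obs: pd.DataFrame, m: int = DEFAULT_FAMILY_SIZE) -> pd.DataFrame:
    """ANOVA F, raw p and Bonferroni-corrected p for every cell."""
    rows = []
    for band in BAND_NAMES:
        for ch in CHANNELS:
            for state in STATES:
                res = anova_emotions(obs, band, ch, state)
                rows.append({"band": band, "channel": ch, "state": state,
                             "F": res["F"], "p": res["p"]})
    df = pd.DataFrame(rows)
    df["p_corrected"] = bonferroni(df["p"].to_numpy(), m)
    return df


def significance_report(obs: pd.DataFrame, alpha: float = 0.05,
                        m: int = DEFAULT_FAMILY_SIZE) -> dict:
    """Full rendering: ANOVA table plus the per-state grids of 6x6 masks."""
    table = significance_table(obs, m)
    masks: dict[str, dict[tuple[str, str], pd.DataFrame]] = {}
    pvals: dict[str, dict[tuple[str, str], pd.DataFrame]] = {}
    for state in STATES:
        masks[state] = {}
        pvals[state] = {}
        for band in BAND_NAMES:
            for ch in CHANNELS:
                pdf, mask = pairwise_ttests(obs, band, ch, state, alpha=alpha)
                masks[state][(band, ch)] = mask
                pvals[state][(band, ch)] = pdf
    for state in STATES:
        if len(masks[state]) != len(BAND_NAMES) * len(CHANNELS):
            raise ValueError("incomplete band x channel grid")
    return {"anova": table, "masks": masks, "pairwise_p": pvals, "alpha": alpha}
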