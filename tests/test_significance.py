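"""ANOVA oracle, Bonferroni arithmetic, pairwise masks, calibration."""

import numpy as np
import pandas as pd
import pytest

from eegmusic.bands import BAND_NAMES, CHANNELS, EMOTIONS
from eegmusic.significance import (
    anova_emotions,
    band_sd_observations,
    bonferroni,
    pairwise_ttests,
    significance_report,
    significance_table,
    type1_calibration,
)


def obs_frame(groups, band="alpha", channel="Fp1", state="speaking"):
    rows = []
    for emo, vals in zip(EMOTIONS, groups):
        for i, v in enumerate(vals):
            rows.append({"subject_id": f"S{i}", "emotion": emo, "state": state,
                         "channel": channel, "band": band, "window_start": 40.0,
                         "sd": float(v)})
    return pd.DataFrame(rows)


def anova_bruteforce(groups):
    """Independent sums-of-squares oracle for one-way fixed-effects ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    from scipy.stats import f as fdist

    F = (ssb / dfb) / (ssw / dfw)
    return F, float(fdist.sf(F, dfb, dfw))


class TestAnova:
    def test_hand_dataset_f_equals_three(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
        F_ref, p_ref = anova_bruteforce(groups)
        assert F_ref == pytest.approx(3.0)
        obs = obs_frame(groups[:3])
        res = anova_emotions(obs, "alpha", "Fp1", "speaking")
        assert res["F"] == pytest.approx(3.0)
        assert res["p"] == pytest.approx(p_ref)

    def test_equal_group_means_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        obs = obs_frame([g, g + 0.0, g[::-1], g, g, g])
        res = anova_emotions(obs, "alpha", "Fp1", "speaking")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.normal(0, 1), 1, rng.integers(5, 15))
                  for _ in range(6)]
        obs = obs_frame(groups)
        res = anova_emotions(obs, "alpha", "Fp1", "speaking")
        F_ref, p_ref = anova_bruteforce(groups)
        assert res["F"] == pytest.approx(F_ref, rel=1e-10)
        assert res["p"] == pytest.approx(p_ref, rel=1e-8)

    def test_undersized_group_rejected(self):
        groups = [np.array([1.0])] + [np.array([1.0, 2.0])] * 5
        with pytest.raises(ValueError):
            anova_emotions(obs_frame(groups), "alpha", "Fp1", "speaking")

    def test_synthetic_effect_detected_on_sensitive_channels(self):
        # strong emotion effect: sensitive midline channels show tiny p
        from eegmusic.pipeline import extract_features
        from eegmusic.synth import GeneratorConfig

        cfg = GeneratorConfig(n_subjects=8, seed=3, effect_size=3.0)
        _, obs = extract_features(cfg, families=())
        for ch in ("Fp1", "Fz", "Fp2"):
            res = anova_emotions(obs, "gamma", ch, "speaking")
            assert res["p"] < 0.001


class TestBonferroni:
    def test_study_mapping_alpha_fp1_quiet(self):
        assert bonferroni(0.0005, 50) == pytest.approx(0.025)

    def test_study_mapping_beta_f8_quiet(self):
        assert bonferroni(0.0093, 50) == pytest.approx(0.465)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 2) == 1.0
        assert bonferroni(0.5, 1000) == 1.0

    def test_monotone_and_linear_below_cap(self, rng):
        p = np.sort(rng.uniform(0, 0.01, 20))
        out = bonferroni(p, 50)
        assert np.all(np.diff(out) >= 0)
        below = 50 * p <= 1
        np.testing.assert_allclose(out[below] / p[below], 50)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestPairwise:
    def test_identical_groups_not_significant(self):
        g = np.arange(10.0)
        obs = obs_frame([g] * 6)
        pmat, mask = pairwise_ttests(obs, "alpha", "Fp1", "speaking")
        assert pmat.iloc[0, 1] == pytest.approx(1.0)
        assert mask.to_numpy().sum() == 0

    def test_mask_symmetric(self, rng):
        groups = [rng.normal(i * 0.5, 1, 12) for i in range(6)]
        _, mask = pairwise_ttests(obs_frame(groups), "alpha", "Fp1", "speaking")
        np.testing.assert_array_equal(mask.to_numpy(), mask.to_numpy().T)

    def test_matches_scipy_welch_flag(self, rng):
        from scipy.stats import ttest_ind

        groups = [rng.normal(0, 1 + i, 10) for i in range(6)]
        pmat, _ = pairwise_ttests(obs_frame(groups), "alpha", "Fp1", "speaking",
                                  equal_var=False)
        ref = ttest_ind(groups[0], groups[1], equal_var=False).pvalue
        assert pmat.iloc[0, 1] == pytest.approx(ref)

    def test_null_false_positive_rate(self, rng):
        # 300 null pairs at alpha = 0.05
        hits = 0
        for _ in range(300):
            a, b = rng.standard_normal((2, 15))
            groups = [a, b] + [rng.standard_normal(15)] * 4
            pmat, _ = pairwise_ttests(obs_frame(groups), "alpha", "Fp1",
                                      "speaking")
            hits += pmat.iloc[0, 1] < 0.05
        assert hits / 300 == pytest.approx(0.05, abs=0.03)


class TestReport:
    @pytest.fixture(scope="class")
    def observations(self):
        rng = np.random.default_rng(9)
        rows = []
        for band in BAND_NAMES:
            for ch in CHANNELS:
                for state in ("speaking", "quiet"):
                    for emo in EMOTIONS:
                        for i in range(6):
                            rows.append({
                                "subject_id": f"S{i}", "emotion": emo,
                                "state": state, "channel": ch, "band": band,
                                "window_start": 40.0,
                                "sd": float(rng.normal(5, 1))})
        return pd.DataFrame(rows)

    def test_grid_of_25_matrices_per_state(self, observations):
        report = significance_report(observations)
        for state in ("speaking", "quiet"):
            assert len(report["masks"][state]) == 25
            for mask in report["masks"][state].values():
                assert mask.shape == (6, 6)  # 36 cells

    def test_anova_table_covers_50_cells(self, observations):
        table = significance_table(observations)
        assert len(table) == 50
        assert (table["p_corrected"] >= table["p"] - 1e-12).all()

    def test_band_sd_observations_shape(self, analysis_set):
        obs = band_sd_observations(analysis_set)
        # slices x channels x bands rows
        assert len(obs) == len(analysis_set) * 5 * 5
        assert (obs["sd"] > 0).all()

    def test_sd_scales_with_signal(self, analysis_set):
        import copy

        scaled = [copy.deepcopy(s) for s in analysis_set[:1]]
        scaled[0].signal = 2.0 * scaled[0].signal
        a = band_sd_observations(analysis_set[:1])["sd"].to_numpy()
        b = band_sd_observations(scaled)["sd"].to_numpy()
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-10)


class TestCalibration:
    def test_type1_rate_near_nominal(self):
        rate = type1_calibration(n_reps=200, seed=11)
        assert rate == pytest.approx(0.05, abs=0.035)
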