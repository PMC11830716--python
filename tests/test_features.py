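"""Feature families: frozen examples, Parseval, packet-tree oracles."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eegmusic.features import (
    FAMILIES,
    PSD_BIN_EDGES,
    assemble,
    band_leaf_ranks,
    extract_all,
    natural_index,
    psd,
    stat_features,
    wp_band_features,
    wp_decompose,
)

finite_signals = hnp.arrays(
    np.float64,
    st.integers(min_value=8, max_value=256),
    elements=st.floats(-1e3, 1e3, allow_nan=False),
)


class TestStatFeatures:
    def test_hand_example(self):
        f = stat_features([1, 2, 3, 4, 5])
        assert f["mean"] == pytest.approx(3.0)
        assert f["variance"] == pytest.approx(2.5)
        assert f["sd"] == pytest.approx(1.5811388300841898)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["kurtosis"] == pytest.approx(-1.2)
        assert f["avg_power"] == pytest.approx(11.0)

    def test_symmetric_signal_zero_skew(self, rng):
        half = rng.normal(0, 1, 100)
        x = np.concatenate([half, -half]) + 3.0
        assert stat_features(x)["skewness"] == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 2, 50)
        a, b = stat_features(x), stat_features(x + 17.0)
        for key in ("variance", "sd", "skewness", "kurtosis"):
            assert a[key] == pytest.approx(b[key])

    def test_scaling_behaviour(self, rng):
        x = rng.normal(0, 1, 64)
        a, b = stat_features(x), stat_features(3.0 * x)
        assert b["variance"] == pytest.approx(9.0 * a["variance"])
        assert b["skewness"] == pytest.approx(a["skewness"])
        assert b["kurtosis"] == pytest.approx(a["kurtosis"])

    def test_error_cases(self):
        with pytest.raises(ValueError):
            stat_features([1, 2, 3])
        with pytest.raises(ValueError):
            stat_features([2.0, 2.0, 2.0, 2.0])


class TestPsd:
    def test_dc_signal(self):
        P = psd([1.0, 1.0, 1.0, 1.0])
        assert P[0] == pytest.approx(4.0)
        assert np.allclose(P[1:], 0.0, atol=1e-12)

    def test_nyquist_alternation(self):
        P = psd([1.0, -1.0, 1.0, -1.0])
        assert P[2] == pytest.approx(4.0)
        assert P[0] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(finite_signals)
    def test_parseval(self, x):
        assert np.sum(psd(x)) == pytest.approx(np.sum(x**2), rel=1e-9, abs=1e-6)

    def test_scaling(self, rng):
        x = rng.normal(0, 1, 32)
        np.testing.assert_allclose(psd(3.0 * x), 9.0 * psd(x))

    def test_too_short(self):
        with pytest.raises(ValueError):
            psd([1.0])


class TestWaveletPacket:
    def test_impulse_response_matches_filters(self):
        x = np.zeros(64)
        x[0] = 1.0
        tree = wp_decompose(x, level=1)
        w = pywt.Wavelet("db4")
        h, g = np.array(w.dec_lo), np.array(w.dec_hi)
        np.testing.assert_allclose(tree.nodes[(1, 0)][:4], h[[0, 2, 4, 6]],
                                   atol=1e-12)
        np.testing.assert_allclose(tree.nodes[(1, 1)][:4], g[[0, 2, 4, 6]],
                                   atol=1e-12)

    def test_zero_signal_all_zero(self):
        tree = wp_decompose(np.zeros(256), level=4)
        assert all(np.allclose(v, 0) for v in tree.nodes.values())

    @pytest.mark.parametrize("level", [1, 4, 8])
    def test_energy_conservation(self, rng, level):
        x = rng.standard_normal(1280)
        tree = wp_decompose(x, level=level)
        e = sum(np.sum(tree.nodes[(level, i)] ** 2) for i in range(2**level))
        assert e == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_matches_pywt_level_one(self, rng):
        # independent route: pywt periodization; equal up to a circular
        # shift of the coefficient sequence, so compare energies exactly
        # and coefficients after alignment
        x = rng.standard_normal(256)
        tree = wp_decompose(x, level=1)
        a_ref, d_ref = pywt.dwt(x, "db4", mode="periodization")
        a = tree.nodes[(1, 0)]
        assert np.sum(a**2) == pytest.approx(np.sum(a_ref**2), rel=1e-10)
        shifts = [s for s in range(len(a)) if np.allclose(np.roll(a, s), a_ref)]
        assert len(shifts) == 1

    def test_total_energy_matches_pywt_deep(self, rng):
        x = rng.standard_normal(1280)
        tree = wp_decompose(x, level=6)
        wp = pywt.WaveletPacket(x, "db4", mode="periodization", maxlevel=6)
        theirs = sum(np.sum(nd.data**2) for nd in wp.get_level(6))
        mine = sum(np.sum(l**2) for l in tree.leaves_natural())
        assert mine == pytest.approx(theirs, rel=1e-8)

    def test_tone_lands_in_correct_frequency_leaf(self):
        fs, n = 256, 1280
        for f0 in (6.0, 10.0, 21.0, 35.0):
            x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
            tree = wp_decompose(x, level=8)
            leaves = tree.leaves_frequency()
            k = int(np.argmax([np.mean(l**2) for l in leaves]))
            assert k * 0.5 <= f0 <= (k + 1) * 0.5 + 0.5

    def test_gray_code_ordering(self):
        assert [natural_index(f, 2) for f in range(4)] == [0, 1, 3, 2]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            wp_decompose(np.zeros(100), level=8)


class TestBandLeaves:
    def test_leaf_counts(self):
        ranks = band_leaf_ranks(level=8, fs=256)
        assert len(ranks["alpha"]) == 12
        assert len(ranks["gamma"]) == 28
        assert len(ranks["delta"]) == 7
        assert len(ranks["theta"]) == 8
        assert len(ranks["beta"]) == 32

    def test_bands_disjoint(self):
        ranks = band_leaf_ranks(level=8, fs=256)
        seen = [f for idxs in ranks.values() for f in idxs]
        assert len(seen) == len(set(seen))

    def test_band_features_shapes(self, rng):
        tree = wp_decompose(rng.standard_normal(1280), level=8)
        feats = wp_band_features(tree)
        assert {b: len(v) for b, v in feats.items()} == {
            "delta": 7, "theta": 8, "alpha": 12, "beta": 32, "gamma": 28}
        raw = wp_band_features(tree, summary="coeffs")
        assert len(raw["alpha"]) == 12 * 5  # 12 leaves x 5 coefficients


class TestAssemble:
    def test_stats_family_is_150_columns(self, analysis_set):
        fm = assemble(analysis_set, "stats")
        assert fm.X.shape == (len(analysis_set), 150)
        assert np.all(np.isfinite(fm.X))

    def test_all_families_align(self, analysis_set):
        feats = extract_all(analysis_set, FAMILIES)
        shapes = {f: feats[f].X.shape[0] for f in FAMILIES}
        assert set(shapes.values()) == {len(analysis_set)}
        for f in FAMILIES:
            np.testing.assert_array_equal(feats[f].y, feats["stats"].y)

    def test_rows_deterministically_ordered(self, analysis_set):
        a = assemble(analysis_set, "stats")
        b = assemble(list(reversed(analysis_set)), "stats")
        np.testing.assert_allclose(a.X, b.X)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            assemble([], "stats")

    def test_csv_roundtrip(self, analysis_set, tmp_path):
        fm = assemble(analysis_set, "psd")
        fm.to_csv(tmp_path / "psd.csv")
        from eegmusic.features import FeatureMatrix

        back = FeatureMatrix.from_csv(tmp_path / "psd.csv", family="psd")
        np.testing.assert_allclose(back.X, fm.X, rtol=1e-12)
        np.testing.assert_array_equal(back.y, fm.y)
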