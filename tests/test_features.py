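"""Spectral/connectivity features and the conventional-ML harness."""

import numpy as np
import pandas as pd
import pytest

from stresswin import (
    BandSet,
    FeatureConfig,
    FeatureTable,
    SynthSpec,
    asymmetry_features,
    band_power,
    coherence,
    extract_features,
    fit_baselines,
    generate_recording,
    power_ratios,
    relative_power,
    subject_split,
)
from stresswin.features import BANDS_WITH_DELTA, _coherence_matrix_welch
from stresswin.labeling import NON_STRESS, STRESS


def _sine(freq, fs=500.0, seconds=10.0, amp=1.0, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandPower:
    def test_sinusoid_closed_form(self):
        amp = 40.0
        seg = np.tile(_sine(10.0, amp=amp), (3, 1))
        p = band_power(seg, (8.0, 12.0), 500.0)
        np.testing.assert_allclose(p, amp**2 / 2, rtol=0.05)

    def test_zero_signal_zero_power_all_bands(self):
        seg = np.zeros((19, 5000))
        for name in BANDS_WITH_DELTA.names:
            assert np.all(band_power(seg, BANDS_WITH_DELTA.edges(name), 500.0) == 0)

    def test_white_noise_band_fraction(self):
        """Flat spectrum: alpha power ~ (band width / Nyquist) x total power."""
        rng = np.random.default_rng(0)
        seg = rng.standard_normal((4, 100_000))
        p_alpha = band_power(seg, (8.0, 12.0), 500.0)
        total = np.var(seg, axis=1)
        expected = (12.0 - 8.0) / 250.0 * total
        np.testing.assert_allclose(p_alpha, expected, rtol=0.2)

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros((2, 100)), (100.0, 300.0), 500.0)

    def test_short_segment_uses_filtered_variance(self):
        seg = np.tile(_sine(10.0, seconds=0.04, amp=10.0), (2, 1))  # 20 samples
        p = band_power(seg, (8.0, 12.0), 500.0)
        assert p.shape == (2,) and np.all(p >= 0)


class TestRelativePowerAndRatios:
    def test_equal_powers(self):
        powers = {b: np.ones(3) for b in ("theta", "alpha", "beta", "delta")}
        rel = relative_power(powers)
        for v in rel.values():
            np.testing.assert_allclose(v, 0.25)
        ratios = power_ratios(powers, ["theta", "alpha", "beta", "delta"])
        assert len(ratios) == 6
        for v in ratios.values():
            np.testing.assert_allclose(v, 1.0, rtol=1e-9)

    def test_relative_powers_sum_to_one(self):
        rng = np.random.default_rng(1)
        powers = {b: rng.random(5) + 0.1 for b in ("theta", "alpha", "beta")}
        rel = relative_power(powers)
        np.testing.assert_allclose(sum(rel.values()), 1.0)

    def test_specific_ratio(self):
        powers = {"alpha": np.array([2.0]), "beta": np.array([1.0])}
        assert abs(power_ratios(powers, ["alpha", "beta"])["alpha/beta"][0] - 2.0) < 1e-9

    def test_zero_channel_rejected(self):
        with pytest.raises(ValueError, match="zero total power"):
            relative_power({"alpha": np.zeros(2), "beta": np.zeros(2)})


class TestCoherence:
    def test_identical_channels_coherence_one(self):
        x = _sine(10.0) + 0.1 * np.random.default_rng(0).standard_normal(5000)
        seg = np.stack([x, x])
        c = coherence(seg, (0, 1), (8.0, 12.0), 500.0, mode="welch")
        assert c > 0.99

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(1)
        seg = rng.standard_normal((2, 5000))
        c = coherence(seg, (0, 1), (8.0, 12.0), 500.0, mode="welch")
        assert c < 0.2

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        seg = np.stack([x, 3.7 * x])
        assert coherence(seg, (0, 1), (8.0, 12.0), 500.0, mode="welch") > 0.99

    def test_symmetric_in_channel_order(self):
        rng = np.random.default_rng(3)
        seg = rng.standard_normal((2, 4000))
        a = coherence(seg, (0, 1), (8.0, 12.0), 500.0)
        b = coherence(seg, (1, 0), (8.0, 12.0), 500.0)
        assert abs(a - b) < 1e-12

    def test_too_short_for_welch_directs_to_surrogate(self):
        seg = np.zeros((2, 20))
        with pytest.raises(ValueError, match="surrogate"):
            coherence(seg, (0, 1), (8.0, 12.0), 500.0, mode="welch")

    def test_matrix_estimator_matches_scipy_pairwise(self):
        """The vectorised all-pairs Welch coherence agrees with scipy's
        per-pair estimator (independent route)."""
        from scipy.signal import coherence as scipy_coherence

        rng = np.random.default_rng(4)
        shared = rng.standard_normal(6000)
        seg = rng.standard_normal((3, 6000)) + 0.8 * shared
        freqs, mat = _coherence_matrix_welch(seg, 500.0, nperseg=500)
        f2, ref = scipy_coherence(seg[0], seg[2], fs=500.0, nperseg=500)
        np.testing.assert_allclose(freqs, f2)
        np.testing.assert_allclose(mat[:, 0, 2], ref, atol=1e-10)


class TestAsymmetry:
    def test_symmetric_powers_zero(self, montage):
        powers = {"alpha": np.ones(19)}
        out = asymmetry_features(powers, list(montage.left_right_pairs), list(montage.channel_names))
        assert all(abs(v) < 1e-9 for v in out.values())

    def test_e_fold_gives_unity(self, montage):
        powers = {"alpha": np.ones(19)}
        powers["alpha"][1] = np.e  # Fp2
        out = asymmetry_features(powers, [("Fp1", "Fp2")], list(montage.channel_names))
        assert abs(out["asym[alpha,Fp1-Fp2]"] - 1.0) < 1e-6

    def test_aas_pair_excluded_when_flagged(self, montage):
        powers = {"alpha": np.ones(19), "beta": np.ones(19)}
        out = asymmetry_features(
            powers, list(montage.left_right_pairs), list(montage.channel_names),
            exclude_aas_pair=True,
        )
        assert "asym[alpha,Fp1-Fp2]" not in out
        assert "asym[beta,Fp1-Fp2]" in out  # only the alpha prefrontal pair is the label source

    def test_unknown_pair_rejected(self, montage):
        with pytest.raises(KeyError):
            asymmetry_features({"alpha": np.ones(19)}, [("XX", "YY")], list(montage.channel_names))


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = SynthSpec(n_subjects=4, session_length=8.0, asym_relax=4.0,
                     asym_stress=0.25, noise_amplitude=5.0, seed=21)
    return [generate_recording(spec, i) for i in range(4)]


class TestExtractFeatures:
    def test_batch_mode_row_and_column_counts(self, tiny_cohort):
        table = extract_features(tiny_cohort[0], "batch_session")
        assert table.n_rows == 2  # two sessions
        n_bands = 4
        power_cols = [c for c in table.feature_names if c.startswith("power[")]
        assert len(power_cols) == n_bands * 19
        assert set(table.label) == {STRESS, NON_STRESS}

    def test_window_mode_row_count_and_no_nan(self, tiny_cohort):
        table = extract_features(tiny_cohort[0], "window_40ms")
        assert table.n_rows == 400  # 16 s at 25 windows/s
        assert not table.frame.isna().any().any()

    def test_window_mode_surrogate_coherence_naming(self, tiny_cohort):
        table = extract_features(tiny_cohort[0], "window_40ms")
        assert any(c.startswith("cohw[") for c in table.feature_names)
        assert not any(c.startswith("coh[") for c in table.feature_names)

    def test_relative_powers_sum_to_one_per_channel(self, tiny_cohort):
        table = extract_features(tiny_cohort[0], "window_40ms")
        cols = [f"relpower[{b},Cz]" for b in ("theta", "alpha", "beta")]
        sums = table.frame[cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-4)

    def test_unknown_mode_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="unknown mode"):
            extract_features(tiny_cohort[0], "batch")


class TestFitBaselines:
    def _separable_table(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(n) < 0.5, STRESS, NON_STRESS).astype(object)
        x = rng.standard_normal((n, 5))
        x[:, 0] += np.where(y == STRESS, 4.0, -4.0)
        subjects = np.array([f"s{i % 6}" for i in range(n)], dtype=object)
        frame = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        return FeatureTable(frame=frame, label=y, subject=subjects, segment=np.arange(n))

    def _split(self):
        return subject_split([f"s{i}" for i in range(6)], 4, 1, 1, seed=0)

    def test_linearly_separable_all_algos(self):
        table = self._separable_table()
        reports = fit_baselines(table, self._split(), seed=0)
        for algo, rep in reports.items():
            assert rep.accuracy >= 0.95, algo

    def test_label_shuffle_gives_chance(self):
        table = self._separable_table(n=12_000, seed=1)
        rng = np.random.default_rng(2)
        table.label = table.label[rng.permutation(len(table.label))]
        reports = fit_baselines(table, self._split(), seed=0,
                                algos=("logistic_regression",))
        assert abs(reports["logistic_regression"].accuracy - 0.5) <= 0.05

    def test_unknown_algo_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_baselines(self._separable_table(), self._split(), algos=("mlp",))

    def test_single_class_training_rejected(self):
        table = self._separable_table()
        table.label[:] = STRESS
        with pytest.raises(ValueError, match="single class"):
            fit_baselines(table, self._split())
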