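"""Feature definitions: hand oracles, brute-force equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transfeat as tf
from transfeat.features import (bvp_features, gsr_features, hrv_freq, hrv_time,
                                multiscale_entropy, sample_entropy)
from transfeat.preprocess import BeatAnnotations, EDAComponents
from transfeat.simulate import StateEffect

from conftest import noise_free_config
from oracles import coarse_grain_bruteforce, sample_entropy_bruteforce


class TestHrvTime:
    def test_hand_computed_example(self):
        out = hrv_time(np.array([0.8, 0.9, 0.8, 0.9]))
        assert out["MEANRR"] == pytest.approx(0.85)
        assert out["RMSSD"] == pytest.approx(0.1)
        assert out["NN50"] == 3
        assert out["PNN50"] == pytest.approx(1.0)
        assert out["HR"] == pytest.approx(70.588, abs=1e-3)
        assert out["SDNN"] == pytest.approx(np.std([0.8, 0.9, 0.8, 0.9], ddof=1))

    def test_constant_series(self):
        out = hrv_time(np.full(10, 0.75))
        assert out["SDNN"] == 0 and out["RMSSD"] == 0
        assert out["NN50"] == 0 and out["PNN50"] == 0
        assert out["HR"] == pytest.approx(80.0)

    def test_nn50_strict_inequality(self):
        out = hrv_time(np.array([0.8, 0.85, 0.8, 0.85]))   # diffs exactly 50 ms
        assert out["NN50"] == 0

    def test_too_few_intervals_missing(self):
        out = hrv_time(np.array([0.8, 0.9]))
        assert all(np.isnan(v) for v in out.values())

    def test_scale_equivariance(self, rng):
        rr = 0.8 + 0.05 * rng.standard_normal(50)
        a, b = hrv_time(rr), hrv_time(2.0 * rr)
        assert b["MEANRR"] == pytest.approx(2 * a["MEANRR"])
        assert b["SDNN"] == pytest.approx(2 * a["SDNN"])
        assert b["RMSSD"] == pytest.approx(2 * a["RMSSD"])
        assert b["HR"] == pytest.approx(a["HR"] / 2)


class TestHrvFreq:
    @staticmethod
    def modulated_rr(freq_hz: float, amp: float, duration: float = 120.0):
        rr, t = [], 0.0
        while t < duration:
            val = 0.8 + amp * np.sin(2 * np.pi * freq_hz * t)
            rr.append(val)
            t += val
        return np.asarray(rr)

    def test_hf_modulation_dominates_hf_band(self):
        out = hrv_freq(self.modulated_rr(0.25, 0.05))
        assert out["HF"] > 10 * out["LF"]

    def test_lf_modulation_gives_ratio_above_one(self):
        out = hrv_freq(self.modulated_rr(0.10, 0.05))
        assert out["LF_HF"] > 1

    def test_constant_rr_near_zero_power(self):
        out = hrv_freq(np.full(100, 0.8))
        assert out["VLF"] == pytest.approx(0, abs=1e-12)
        assert out["LF"] == pytest.approx(0, abs=1e-12)
        assert out["HF"] == pytest.approx(0, abs=1e-12)
        assert np.isnan(out["LF_HF"])

    def test_band_powers_bounded_by_variance(self, rng):
        for _ in range(5):
            rr = 0.8 + 0.03 * rng.standard_normal(150)
            out = hrv_freq(rr)
            total = out["VLF"] + out["LF"] + out["HF"]
            assert total >= 0
            assert total <= np.var(rr) * 1.05 * 4  # loose: Welch vs raw variance


class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(50, 3.3)) == 0.0

    def test_periodic_all_matches_extend(self):
        x = np.array([1.0, 2.0, 3.0] * 20)
        assert sample_entropy(x, r=0.3) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 300))
            x = rng.standard_normal(n)
            ours = sample_entropy(x)
            oracle = sample_entropy_bruteforce(x)
            if np.isnan(oracle):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-10)

    def test_affine_invariance_with_relative_r(self, rng):
        x = rng.standard_normal(100)
        assert sample_entropy(3.0 * x + 7.0) == pytest.approx(sample_entropy(x),
                                                              abs=1e-10)

    def test_too_short_missing(self):
        assert np.isnan(sample_entropy(np.array([1.0, 2.0, 3.0])))


class TestMultiscaleEntropy:
    def test_scale_one_is_plain_sample_entropy(self, rng):
        x = 0.8 + 0.02 * rng.standard_normal(80)
        out = multiscale_entropy(x)
        assert out["MSE1"] == pytest.approx(sample_entropy(x), abs=1e-12)

    def test_constant_all_scales_zero(self):
        out = multiscale_entropy(np.full(60, 0.8))
        assert all(v == 0.0 for v in out.values())

    def test_matches_bruteforce_coarse_grain(self, rng):
        x = 0.8 + 0.03 * rng.standard_normal(90)
        # AR(1)-flavoured smoothing so high scales keep structure
        x = np.convolve(x, np.ones(3) / 3, mode="valid")
        r = 0.2 * np.std(x, ddof=1)
        out = multiscale_entropy(x)
        for tau in range(2, 6):
            coarse = coarse_grain_bruteforce(x, tau)
            oracle = sample_entropy_bruteforce(coarse, r=r)
            if np.isnan(oracle):
                assert np.isnan(out[f"MSE{tau}"])
            else:
                assert out[f"MSE{tau}"] == pytest.approx(oracle, abs=1e-10)


class TestBvpFeatures:
    @staticmethod
    def annotations(n=20, rr=0.8, amp=1.0):
        peaks = np.arange(1, n + 1) * rr
        onsets = peaks - 0.25
        return BeatAnnotations(event_times_s=peaks, onset_times_s=onsets,
                               peak_times_s=peaks,
                               amplitudes=np.full(n, amp),
                               peak_values=np.full(n, amp),
                               widths_s=np.diff(onsets))

    def test_constant_amplitudes(self):
        out = bvp_features(self.annotations(), (0.0, 60.0))
        assert out["STDPA_BVP"] == 0
        assert out["MAXPA_BVP"] == out["MEANPA_BVP"] == 1.0

    def test_same_formula_as_ecg_sdnn(self, rng):
        rr = 0.8 + 0.04 * rng.standard_normal(40)
        peaks = np.cumsum(rr) + 1.0
        ann = BeatAnnotations(event_times_s=peaks, onset_times_s=peaks - 0.2,
                              peak_times_s=peaks,
                              amplitudes=np.ones(40), peak_values=np.ones(40),
                              widths_s=np.diff(peaks - 0.2))
        out = bvp_features(ann, (0.0, float(peaks[-1] + 1)))
        expected = hrv_time(np.diff(peaks))
        assert out["SDNN_BVP"] == pytest.approx(expected["SDNN"])
        assert out["MEANRR_BVP"] == pytest.approx(expected["MEANRR"])
        assert out["PR_BVP"] == pytest.approx(expected["HR"])

    def test_h_w_is_amplitude_over_width(self):
        out = bvp_features(self.annotations(rr=0.8, amp=1.0), (0.0, 60.0))
        assert out["H_W_BVP"] == pytest.approx(1.0 / 0.8)
        assert out["WIDTH_BVP"] == pytest.approx(0.8)


class TestGsrFeatures:
    def test_constant_tonic_no_events(self):
        n = 240
        eda = EDAComponents(4.0, np.full(n, 2.5), np.zeros(n), [])
        out = gsr_features(eda, (0.0, 60.0))
        assert out["MEANT_GSR"] == pytest.approx(2.5)
        assert out["STDT_GSR"] == 0
        assert out["NUMP_GSR"] == 0
        for k in ("MAXPA", "MEANPA", "STDPA", "MEANPR", "STDPR"):
            assert out[f"{k}_GSR"] == 0

    def test_single_event_statistics(self):
        n = 240
        eda = EDAComponents(4.0, np.zeros(n), np.zeros(n),
                            [(10.0, 11.2, 0.5, 1.2)])
        out = gsr_features(eda, (0.0, 60.0))
        assert out["NUMP_GSR"] == 1
        assert out["MAXPA_GSR"] == out["MEANPA_GSR"] == pytest.approx(0.5)
        assert out["MEANPR_GSR"] == pytest.approx(1.2)
        assert out["STDPA_GSR"] == 0 and out["STDPR_GSR"] == 0

    def test_normalisation_changes_tonic_scale_only(self):
        n = 240
        tonic = 5.0 + 0.1 * np.sin(np.linspace(0, 3, n))
        eda = EDAComponents(4.0, tonic, np.zeros(n), [])
        raw = gsr_features(eda, (0.0, 60.0))
        stats = {"tonic": (5.0, 0.1), "phasic": (0.0, 1.0)}
        norm = gsr_features(eda, (0.0, 60.0), norm_stats=stats)
        assert norm["MEANT_GSR"] == pytest.approx((raw["MEANT_GSR"] - 5.0) / 0.1)
        assert norm["NUMP_GSR"] == raw["NUMP_GSR"]


class TestExtraction:
    def test_matrix_shape_and_window_count(self, fm3):
        assert list(fm3.columns[4:]) == list(tf.FEATURE_COLUMNS)
        assert fm3.shape[1] == 4 + 39
        per_seg = fm3[fm3.label == "neutral"].groupby("subject").size()
        assert (per_seg == 181).all()

    def test_no_missing_after_imputation(self, fm3):
        assert not fm3[list(tf.FEATURE_COLUMNS)].isna().any().any()

    def test_deterministic(self, cohort3, fm3):
        again = tf.extract_feature_matrix([cohort3[0]])
        ref = fm3[fm3.subject == 0].reset_index(drop=True)
        assert np.allclose(again[list(tf.FEATURE_COLUMNS)].to_numpy(),
                           ref[list(tf.FEATURE_COLUMNS)].to_numpy(),
                           equal_nan=True)

    def test_noise_free_planted_recovery(self):
        cfg = noise_free_config(seed=4)
        subj = tf.simulate_cohort(cfg)[0]
        fm = tf.extract_subject_features(
            subj, tf.ExtractionConfig(filter_ecg=False, filter_bvp=False,
                                      normalize_gsr=False))
        # HR = 60 / 0.8 exactly, every window
        assert np.allclose(fm["HR_ECG"], 75.0, atol=1e-6)
        assert np.allclose(fm["MEANRR_ECG"], 0.8, atol=1e-6)
        assert np.allclose(fm["MEANPA_BVP"], 0.72, atol=1e-6)
        assert np.allclose(fm["MEANT_GSR"], 6.0, atol=1e-3)
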