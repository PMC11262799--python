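"""Stimulus features, ridge TRF estimation, scoring and model comparison."""

import numpy as np
import pandas as pd
import pytest

from neuroshare import trf
from neuroshare.trf import (
    NeuralTarget,
    StimulusFeature,
    cochlear_envelope,
    compare_models,
    cross_validate_lambda,
    fit_trf,
    peak_rate,
    score_trf,
    select_seed,
    zscore,
)


class TestCochlearEnvelope:
    def test_tracks_amplitude_modulator(self, rng):
        fs = 16000.0
        t = np.arange(int(8 * fs)) / fs
        modulator = 1.0 + 0.9 * np.sin(2 * np.pi * 3.0 * t)
        audio = modulator * rng.standard_normal(len(t))
        env = cochlear_envelope(audio, fs)
        mod100 = modulator[:: int(fs // 100)][: len(env)]
        sl = slice(50, -50)
        r = np.corrcoef(env[sl], mod100[sl])[0, 1]
        assert r > 0.95

    def test_silence_gives_zero_envelope(self):
        with pytest.warns(RuntimeWarning, match="silent"):
            env = cochlear_envelope(np.zeros(32000), 16000.0)
        assert np.all(env == 0)

    def test_scale_invariance_after_zscore(self, rng):
        fs = 16000.0
        audio = rng.standard_normal(int(4 * fs))
        e1 = zscore(cochlear_envelope(audio, fs))
        e2 = zscore(cochlear_envelope(7.3 * audio, fs))
        assert np.max(np.abs(e1 - e2)) < 1e-3  # float roundoff only

    def test_stereo_rejected(self, rng):
        with pytest.raises(ValueError, match="mono"):
            cochlear_envelope(rng.standard_normal((2, 32000)), 16000.0)


class TestPeakRate:
    def test_constant_envelope_no_events(self):
        assert np.all(peak_rate(np.full(500, 2.0)).series == 0)

    def test_single_bump_single_event_at_rising_inflection(self):
        t = np.arange(500) / 100.0
        t0, s = 2.5, 0.3
        env = np.exp(-(((t - t0) / s) ** 2))
        events = peak_rate(env).series
        idx = np.flatnonzero(events > 0)
        assert len(idx) == 1
        # derivative of a Gaussian peaks at t0 - s/sqrt(2)
        assert abs(t[idx[0]] - (t0 - s / np.sqrt(2))) < 0.05

    def test_two_bumps_two_events(self):
        t = np.arange(800) / 100.0
        env = np.exp(-(((t - 2.0) / 0.2) ** 2)) + np.exp(-(((t - 5.0) / 0.2) ** 2))
        events = peak_rate(env).series
        assert (events > 0).sum() == 2

    def test_series_is_zscored(self, rng):
        env = np.abs(rng.standard_normal(2000)).cumsum() % 7
        s = peak_rate(env).series
        assert abs(s.mean()) < 1e-9
        assert abs(s.std() - 1) < 1e-6


class TestFitTRF:
    def test_pure_delay_recovered(self, rng):
        s = rng.standard_normal(6000)
        feat = StimulusFeature("envelope", zscore(s))
        y = np.roll(s, 5)
        y[:5] = 0
        model = fit_trf(feat, NeuralTarget("LF", y[None, :]), lam=0.0)
        peak = model.lags_ms[np.argmax(np.abs(model.weights[:, 0]))]
        assert peak == pytest.approx(50.0)
        sc = score_trf(feat, NeuralTarget("LF", y[None, :]), lam=0.0)
        assert sc["r"][0] > 0.99

    def test_lag_grid_matches_contract(self, rng):
        feat = StimulusFeature("envelope", zscore(rng.standard_normal(2000)))
        model = fit_trf(feat, NeuralTarget("LF", rng.standard_normal((1, 2000))), 1.0)
        assert model.n_lags == 116
        assert model.lags_ms[0] == -150.0
        assert model.lags_ms[-1] == 1000.0

    def test_kernel_recovery_at_0db(self, rng):
        s = rng.standard_normal(12000)
        k = __import__("neuroshare.synthgen", fromlist=["default_trf_kernel"]
                       ).default_trf_kernel()
        resp = np.convolve(s, k)[: len(s)]
        noisy = resp + rng.standard_normal(len(s)) * resp.std()
        feat = StimulusFeature("peakRate", zscore(s))
        model = fit_trf(feat, NeuralTarget("LF", noisy[None, :]), lam=50.0)
        lag0 = int(np.argmin(np.abs(model.lags_ms)))
        w = model.weights[lag0 : lag0 + len(k), 0]
        assert np.corrcoef(w, k)[0, 1] >= 0.95

    def test_ridge_shrinkage_limit(self, rng):
        feat = StimulusFeature("envelope", zscore(rng.standard_normal(3000)))
        y = NeuralTarget("LF", rng.standard_normal((1, 3000)))
        small = fit_trf(feat, y, 1.0)
        huge = fit_trf(feat, y, 1e12)
        assert np.linalg.norm(huge.weights) < 1e-4 * np.linalg.norm(small.weights)

    def test_invalid_inputs_rejected(self, rng):
        feat = StimulusFeature("envelope", zscore(rng.standard_normal(1000)))
        y = NeuralTarget("LF", rng.standard_normal((1, 1000)))
        with pytest.raises(ValueError, match=">= 0"):
            fit_trf(feat, y, -1.0)
        with pytest.raises(ValueError, match="length mismatch"):
            fit_trf(feat, NeuralTarget("LF", rng.standard_normal((1, 900))), 1.0)


class TestCrossValidation:
    def test_noiseless_prefers_smallest_lambda(self, rng):
        s = rng.standard_normal(4000)
        y = np.roll(s, 10)[None, :]
        lam = cross_validate_lambda(
            StimulusFeature("envelope", zscore(s)), NeuralTarget("LF", y),
            lambda_grid=(1e-4, 1.0, 1e4, 1e8),
        )
        assert lam == 1e-4

    def test_noisy_collinear_design_prefers_regularization(self, rng):
        # a smooth (autocorrelated) feature makes the lagged design
        # collinear, so OLS overfits badly and CV must pick lambda > min
        from scipy import signal as sg

        s = sg.sosfiltfilt(sg.butter(4, 8, fs=100, output="sos"),
                           rng.standard_normal(1500))
        resp = np.convolve(s, np.hanning(30))[: len(s)]
        y = (resp + 3.0 * resp.std() * rng.standard_normal(len(s)))[None, :]
        lam = cross_validate_lambda(
            StimulusFeature("envelope", zscore(s)), NeuralTarget("LF", y),
            lambda_grid=(1e-6, 1e2, 1e5),
        )
        assert lam > 1e-6

    def test_single_element_grid(self, rng):
        s = rng.standard_normal(2000)
        lam = cross_validate_lambda(
            StimulusFeature("envelope", zscore(s)),
            NeuralTarget("LF", np.roll(s, 3)[None, :]),
            lambda_grid=(7.0,),
        )
        assert lam == 7.0

    def test_empty_grid_rejected(self, rng):
        s = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="non-empty"):
            cross_validate_lambda(
                StimulusFeature("envelope", zscore(s)),
                NeuralTarget("LF", s[None, :]), lambda_grid=(),
            )


class TestScore:
    def test_perfect_prediction_capped_z(self, rng):
        s = rng.standard_normal(5000)
        feat = StimulusFeature("envelope", zscore(s))
        sc = score_trf(feat, NeuralTarget("LF", s[None, :]), lam=0.0)
        assert sc["r"][0] > 0.9999
        assert np.isfinite(sc["fisher_z"][0])

    def test_fisher_z_closed_form(self):
        assert np.arctanh(0.55) == pytest.approx(0.6184, abs=1e-3)

    def test_null_channels_calibrated_after_bh(self, rng):
        s = rng.standard_normal(4000)
        feat = StimulusFeature("envelope", zscore(s))
        y = rng.standard_normal((60, 4000))  # independent white targets
        sc = score_trf(feat, NeuralTarget("LF", y), lam=1e3)
        assert (sc["q"] < 0.05).mean() <= 0.1

    def test_affine_target_invariance(self, rng):
        s = rng.standard_normal(4000)
        resp = np.convolve(s, np.hanning(20))[: len(s)]
        y = resp + rng.standard_normal(len(s))
        feat = StimulusFeature("envelope", zscore(s))
        r1 = score_trf(feat, NeuralTarget("LF", y[None, :]), 10.0)["r"][0]
        r2 = score_trf(feat, NeuralTarget("LF", (5.0 * y - 3.0)[None, :]), 10.0)["r"][0]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_prediction_flagged(self, rng):
        feat = StimulusFeature("envelope", np.zeros(1000))
        sc = score_trf(feat, NeuralTarget("LF", rng.standard_normal((1, 1000))), 1.0)
        assert sc["degenerate"][0]
        assert sc["r"][0] == 0.0
        assert sc["p"][0] == 1.0


class TestModelComparison:
    def test_clear_winner_declared(self, rng):
        pct = pd.DataFrame(
            {
                "peakRate+LF": 40 + rng.uniform(0, 2, 8),
                "envelope+LF": 28 + rng.uniform(0, 2, 8),
                "peakRate+HFa": 5 + rng.uniform(0, 2, 8),
                "envelope+HFa": 5 + rng.uniform(0, 2, 8),
            }
        )
        res = compare_models(pct)
        assert res["winner"] == "peakRate+LF"
        assert res["decisive"]
        assert len(res["pairwise"]) == 3  # three comparisons vs the winner

    def test_identical_models_tie_with_p_one(self, rng):
        x = 30 + rng.uniform(0, 5, 8)
        pct = pd.DataFrame({"a": x, "b": x.copy()})
        res = compare_models(pct)
        assert not res["decisive"]
        assert res["pairwise"]["p"].iloc[0] == 1.0

    def test_all_zero_percentages_no_winner(self):
        pct = pd.DataFrame({"a": np.zeros(8), "b": np.zeros(8)})
        assert compare_models(pct)["winner"] is None


class TestSelectSeed:
    def _scores(self, r, q):
        return pd.DataFrame({"channel": np.arange(len(r)), "r": r, "q": q})

    def test_best_encoding_channel_selected(self):
        sp = self._scores([0.1, 0.5, 0.3], [0.5, 0.001, 0.2])
        mu = self._scores([0.1, 0.4, 0.3], [0.5, 0.002, 0.2])
        assert select_seed(sp, mu) == 1

    def test_tie_breaks_to_lower_index(self):
        sp = self._scores([0.5, 0.5], [0.001, 0.001])
        mu = self._scores([0.5, 0.5], [0.001, 0.001])
        assert select_seed(sp, mu) == 0

    def test_no_significant_channel_excludes_patient(self):
        sp = self._scores([0.1, 0.2], [0.5, 0.4])
        mu = self._scores([0.1, 0.2], [0.5, 0.4])
        assert select_seed(sp, mu) is None
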