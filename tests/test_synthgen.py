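"""Generator contracts: determinism, spectral shape, effect-size realization."""

import numpy as np
import pytest

from neuroshare import preprocess as pre
from neuroshare import spectral, synthgen, trf
from neuroshare.synthgen import (
    ArtifactSpec,
    CategoryEffect,
    CohortConfig,
    Coupling,
    TRFChannelSpec,
    generate_cohort,
    generate_stimulus,
)


class TestStimulus:
    def test_same_seed_bit_identical(self):
        a = generate_stimulus(60, "speech", seed=7, include_audio=True)
        b = generate_stimulus(60, "speech", seed=7, include_audio=True)
        assert np.array_equal(a.envelope, b.envelope)
        assert np.array_equal(a.waveform, b.waveform)

    def test_different_seeds_differ(self):
        a = generate_stimulus(60, "speech", seed=1)
        b = generate_stimulus(60, "speech", seed=2)
        assert not np.array_equal(a.envelope, b.envelope)

    @pytest.mark.parametrize(
        "domain,lo,hi", [("speech", 3.0, 6.0), ("music", 1.0, 3.0)]
    )
    def test_modulation_spectrum_peak(self, domain, lo, hi):
        from scipy import signal as sg

        stim = generate_stimulus(60, domain, seed=1)
        env = stim.envelope - stim.envelope.mean()
        f, power = sg.welch(env, fs=stim.env_rate, nperseg=1024)
        sel = (f > 0.5) & (f < 20)
        peak = f[sel][np.argmax(power[sel])]
        assert lo <= peak <= hi

    def test_speech_modulates_faster_than_music(self):
        def centroid(stim):
            env = stim.envelope - stim.envelope.mean()
            f = np.fft.rfftfreq(len(env), 1.0 / stim.env_rate)
            p = np.abs(np.fft.rfft(env)) ** 2
            sel = (f > 0.5) & (f < 16)
            return (f[sel] * p[sel]).sum() / p[sel].sum()

        s = generate_stimulus(60, "speech", seed=3)
        m = generate_stimulus(60, "music", seed=3)
        assert centroid(s) > centroid(m)

    def test_zero_event_rate_constant_envelope(self):
        stim = generate_stimulus(20, "speech", seed=0, event_rate=0)
        assert np.all(stim.envelope == stim.envelope[0])
        pr = trf.peak_rate(stim.envelope)
        assert np.all(pr.series == 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_stimulus(0, "speech", seed=0)

    def test_waveform_envelope_is_reference(self):
        stim = generate_stimulus(30, "speech", seed=5, include_audio=True)
        # modulation depth: |waveform| averaged in envelope-rate bins tracks env
        n = len(stim.envelope)
        w = np.abs(stim.waveform)
        per = len(w) // n
        coarse = w[: n * per].reshape(n, per).mean(axis=1)
        r = np.corrcoef(coarse, stim.envelope)[0, 1]
        assert r > 0.95


class TestConfigValidation:
    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            CohortConfig(
                channels_per_patient=4,
                category_map={(9, "alpha"): CategoryEffect("shared")},
            )

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            CohortConfig(
                channels_per_patient=4,
                category_map={(1, "ripple"): CategoryEffect("shared")},
            )

    def test_kappa_range_enforced(self):
        with pytest.raises(ValueError, match="kappa"):
            Coupling(seed_channel=0, kappa_speech=1.5)

    def test_duration_must_exceed_epoch(self):
        with pytest.raises(ValueError, match="exceed the epoch length"):
            CohortConfig(run_durations={"speech": 3.0, "music": 60.0,
                                        "baseline_tones": 60.0})

    def test_region_labels_per_channel(self):
        with pytest.raises(ValueError, match="region label"):
            CohortConfig(channels_per_patient=4, region_labels=["a", "b"])


def _tiny_config(**kw):
    defaults = dict(
        n_patients=1,
        channels_per_patient=6,
        run_durations={"speech": 40.0, "music": 40.0, "baseline_tones": 40.0},
        rng_seed=3,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestCohort:
    def test_seed_determinism(self):
        recs1, _, _ = generate_cohort(_tiny_config())
        recs2, _, _ = generate_cohort(_tiny_config())
        recs3, _, _ = generate_cohort(_tiny_config(rng_seed=4))
        key = ("P00", "speech")
        assert np.array_equal(recs1[key].data, recs2[key].data)
        assert not np.array_equal(recs1[key].data, recs3[key].data)

    def test_background_spectral_slope(self):
        recs, _, _ = generate_cohort(_tiny_config(
            run_durations={"speech": 120.0, "music": 10.1, "baseline_tones": 10.1}))
        x = recs[("P00", "speech")].data[0]
        f, p = __import__("scipy.signal", fromlist=["welch"]).welch(
            x, fs=500, nperseg=4096
        )
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert abs(-slope - 1.0) < 0.2

    def test_effect_size_recovered_by_band_power_oracle(self):
        # d = 1.5 selective-speech activation in alpha; >= 100 epochs
        cfg = _tiny_config(
            channels_per_patient=3,
            run_durations={"speech": 510.0, "music": 10.1, "baseline_tones": 510.0},
            category_map={(1, "alpha"): CategoryEffect("selective_speech",
                                                       "activation", 1.5)},
        )
        recs, truth, _ = generate_cohort(cfg)
        bp_s = spectral.band_power(pre.epoch(recs[("P00", "speech")]))
        bp_b = spectral.band_power(pre.epoch(recs[("P00", "baseline_tones")]))
        ls = np.log(bp_s.band("alpha")[:, 1])
        lb = np.log(bp_b.band("alpha")[:, 1])
        pooled_sd = np.sqrt((ls.var(ddof=1) + lb.var(ddof=1)) / 2)
        d_hat = (ls.mean() - lb.mean()) / pooled_sd
        assert abs(d_hat - 1.5) / 1.5 < 0.2

    def test_strong_effect_visible_only_in_target_condition(self):
        cfg = _tiny_config(
            channels_per_patient=3,
            run_durations={"speech": 100.0, "music": 100.0, "baseline_tones": 100.0},
            category_map={(2, "alpha"): CategoryEffect("selective_speech",
                                                       "activation", 3.0)},
        )
        recs, _, _ = generate_cohort(cfg)
        vals = {}
        for cond in ("speech", "music", "baseline_tones"):
            bp = spectral.band_power(pre.epoch(recs[("P00", cond)]))
            vals[cond] = np.log(bp.band("alpha")[:, 2]).mean()
        assert vals["speech"] > vals["baseline_tones"] + 0.3
        assert abs(vals["music"] - vals["baseline_tones"]) < 0.2

    def test_full_coupling_gives_near_unit_coherence(self):
        from neuroshare import connectivity as conn

        cfg = _tiny_config(
            channels_per_patient=4,
            run_durations={"speech": 200.0, "music": 10.1, "baseline_tones": 10.1},
            coupling_map={(3, "theta"): Coupling(seed_channel=0, kappa_speech=1.0,
                                                 power_ratio=200.0)},
        )
        recs, _, _ = generate_cohort(cfg)
        es = pre.epoch(recs[("P00", "speech")])
        c = conn.band_coherence(es, 0, "theta")
        assert c[3] > 0.9

    def test_artifacts_unambiguous_for_detectors(self):
        cfg = _tiny_config(
            channels_per_patient=12,
            run_durations={"speech": 100.0, "music": 10.1, "baseline_tones": 10.1},
            artifact_spec=ArtifactSpec(channel_fraction=0.1, epoch_fraction=0.1),
        )
        recs, truth, _ = generate_cohort(cfg)
        rec = recs[("P00", "speech")]
        mask = pre.detect_artifact_channels(rec)
        flagged_ch = set(int(i) for i in np.flatnonzero(~mask))
        # every injected artifact channel is caught; the 2xIQR rule has a
        # natural false-flag rate on clean channels, so allow a small excess
        assert set(truth.artifact_channels["P00"]) <= flagged_ch
        assert len(flagged_ch) <= len(truth.artifact_channels["P00"]) + 2
        es = pre.epoch(rec)
        es.channel_mask &= mask
        ep_mask = pre.detect_artifact_epochs(es)
        flagged = set(np.flatnonzero(~ep_mask))
        assert set(truth.artifact_epochs[("P00", "speech")]) <= flagged

    def test_trf_injection_reaches_requested_lf_snr(self):
        kernel = tuple(synthgen.default_trf_kernel())
        cfg = _tiny_config(
            channels_per_patient=2,
            run_durations={"speech": 120.0, "music": 10.1, "baseline_tones": 10.1},
            trf_channels={1: TRFChannelSpec(kernel=kernel, feature="peakRate",
                                            snr_db=0.0)},
            bg_std_spread=0.0,
        )
        recs, truth, stimuli = generate_cohort(cfg)
        from scipy import signal as sg

        sos = sg.butter(4, (1, 9), btype="bandpass", fs=500, output="sos")
        lf = sg.sosfiltfilt(sos, recs[("P00", "speech")].data, axis=-1)
        # channel 1 = background + response; channel 0 = background only.
        v_resp = lf[1].var() - lf[0].var()
        ratio = v_resp / lf[0].var()
        assert 10 * np.log10(max(ratio, 1e-12)) == pytest.approx(0.0, abs=1.5)

    def test_ground_truth_serializable(self):
        import json

        cfg = _tiny_config(
            category_map={(0, "delta"): CategoryEffect("shared", "activation", 2.0)},
        )
        _, truth, _ = generate_cohort(cfg)
        payload = json.loads(truth.to_json())
        assert payload["category_map"]["0:delta"]["category"] == "shared"
        assert payload["rng_seed"] == 3
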