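"""Cross-frequency deduction traces and population prevalence."""

import numpy as np
import pandas as pd
import pytest

from neuroshare.aggregate import (
    cross_frequency_selectivity,
    default_band_order,
    population_prevalence,
)
from neuroshare.spectral import DEFAULT_BANDS

BANDS = list(DEFAULT_BANDS.names)


def cat_table(rows):
    """rows: (patient, channel, band, category[, region, direction])"""
    recs = []
    for row in rows:
        patient, channel, band, category = row[:4]
        region = row[4] if len(row) > 4 else "r0"
        direction = row[5] if len(row) > 5 else "activation"
        recs.append(dict(patient=patient, channel=channel, band=band,
                         category=category, region=region, direction=direction))
    return pd.DataFrame(recs)


def full_table(assign, n_channels=4, patients=("P0",)):
    """Category table covering every band; ``assign`` overrides specific
    (patient, channel, band) cells, everything else is 'none'."""
    rows = []
    for p in patients:
        for c in range(n_channels):
            for b in BANDS:
                rows.append((p, c, b, assign.get((p, c, b), "none")))
    return cat_table(rows)


class TestBandOrder:
    def test_wraps_ascending(self):
        assert default_band_order("alpha") == [
            "alpha", "beta", "low_gamma", "hfa", "delta", "theta"]

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            default_band_order("ripple")


class TestDeductionTrace:
    def test_other_domain_response_removes_channel(self):
        df = full_table({
            ("P0", 0, "delta"): "selective_speech",
            ("P0", 0, "theta"): "shared",  # responds to music in theta
            ("P0", 1, "delta"): "selective_speech",
        })
        tr = cross_frequency_selectivity(df, "speech", "delta")
        assert tr["n_remaining"].iloc[0] == 2
        assert tr.set_index("band").loc["theta", "n_remaining"] == 1
        assert tr["n_remaining"].iloc[-1] == 1

    def test_everywhere_selective_survives(self):
        df = full_table({("P0", 0, b): "selective_speech" for b in BANDS})
        tr = cross_frequency_selectivity(df, "speech", "delta")
        assert (tr["n_remaining"] == 1).all()

    def test_empty_start_all_zero(self):
        df = full_table({})
        tr = cross_frequency_selectivity(df, "music", "theta")
        assert (tr["percent"] == 0).all()

    def test_trace_non_increasing_on_random_maps(self, rng):
        cats = ["none", "shared", "selective_speech", "selective_music",
                "preferred_speech", "preferred_music"]
        for _ in range(30):
            assign = {}
            for c in range(12):
                for b in BANDS:
                    assign[("P0", c, b)] = cats[rng.integers(len(cats))]
            df = full_table(assign, n_channels=12)
            for domain in ("speech", "music"):
                tr = cross_frequency_selectivity(df, domain, "delta")
                assert (np.diff(tr["percent"]) <= 1e-12).all()

    def test_own_domain_selectivity_elsewhere_does_not_remove(self):
        # selective to speech in delta AND theta: never responsive to music
        df = full_table({
            ("P0", 0, "delta"): "selective_speech",
            ("P0", 0, "theta"): "selective_speech",
        })
        tr = cross_frequency_selectivity(df, "speech", "delta")
        assert (tr["n_remaining"] == 1).all()

    def test_bad_band_order_rejected(self):
        df = full_table({})
        with pytest.raises(ValueError, match="begin with"):
            cross_frequency_selectivity(df, "speech", "delta",
                                        band_order=["theta", "delta"])


class TestPrevalence:
    def _region_df(self, patient_profiles, band="hfa", region="IPL"):
        """patient_profiles: list of per-patient channel category lists."""
        rows = []
        for i, cats in enumerate(patient_profiles):
            for c, cat in enumerate(cats):
                rows.append((f"P{i}", c, band, cat, region))
        return cat_table(rows)

    def test_worked_seven_patient_pattern(self):
        # one of seven patients all-selective-speech, six mixed -> 1/7 vs 6/7
        profiles = [["selective_speech", "selective_speech"]] + [
            ["selective_speech", "shared"]] * 6
        tab = population_prevalence(self._region_df(profiles))
        row = tab.iloc[0]
        assert row["n_patients"] == 7
        assert row["n_selective_speech"] == 1
        assert row["pct_selective_speech"] == pytest.approx(100 / 7)
        assert row["pct_shared"] == pytest.approx(600 / 7)

    def test_single_patient_region_excluded(self):
        with pytest.warns(RuntimeWarning, match="inclusion rule"):
            tab = population_prevalence(self._region_df([["shared", "shared"]]))
        assert len(tab) == 0

    def test_min_channels_rule(self):
        # second patient has only one significant channel -> not counted
        profiles = [["shared", "shared"], ["shared", "none"]]
        with pytest.warns(RuntimeWarning):
            tab = population_prevalence(self._region_df(profiles))
        assert len(tab) == 0

    def test_mixture_is_shared(self):
        profiles = [["selective_speech", "selective_music"],
                    ["selective_music", "selective_music"]]
        tab = population_prevalence(self._region_df(profiles))
        row = tab.iloc[0]
        assert row["n_shared"] == 1
        assert row["n_selective_music"] == 1

    def test_preferred_channels_excluded_first(self):
        profiles = [["selective_speech", "preferred_music", "selective_speech"],
                    ["selective_speech", "selective_speech", "preferred_speech"]]
        tab = population_prevalence(self._region_df(profiles))
        # after dropping preferred channels both patients are all-speech
        assert tab.iloc[0]["pct_selective_speech"] == 100.0

    def test_direction_disagreement_becomes_shared(self):
        rows = [
            ("P0", 0, "hfa", "selective_speech", "IPL", "activation"),
            ("P0", 0, "hfa", "selective_music", "IPL", "deactivation"),
            ("P0", 1, "hfa", "shared", "IPL", "activation"),
            ("P1", 0, "hfa", "shared", "IPL", "activation"),
            ("P1", 1, "hfa", "shared", "IPL", "activation"),
        ]
        tab = population_prevalence(cat_table(rows))
        assert tab.iloc[0]["n_shared"] == 2

    def test_order_invariance(self, rng):
        profiles = [["selective_speech", "selective_speech"],
                    ["shared", "selective_music"],
                    ["selective_music", "selective_music"]]
        df = self._region_df(profiles)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            population_prevalence(df), population_prevalence(shuffled))

    def test_percentages_sum_to_100(self):
        profiles = [["selective_speech", "selective_speech"],
                    ["shared", "shared"],
                    ["selective_music", "selective_music"]]
        row = population_prevalence(self._region_df(profiles)).iloc[0]
        total = (row["pct_selective_speech"] + row["pct_selective_music"]
                 + row["pct_shared"])
        assert total == pytest.approx(100.0)
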