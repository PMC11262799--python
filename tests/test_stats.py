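"""tmax permutation engine, taxonomy decisions and BH correction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuroshare.spectral import DEFAULT_BANDS, BandPower
from neuroshare.stats import categorize_channels, fdr_bh, tmax_permutation_test


def brute_force_tmax_p(a, b):
    """Independent oracle: enumerate every label split of the pooled epochs
    and count splits whose max |Welch t| over channels reaches the observed
    channel statistic."""
    pooled = np.concatenate([a, b], axis=0)
    n, k = pooled.shape[0], min(a.shape[0], b.shape[0])
    t_obs = sps.ttest_ind(a, b, equal_var=False).statistic
    maxes = []
    for idx in combinations(range(n), k):
        g1 = pooled[list(idx)]
        g2 = pooled[[i for i in range(n) if i not in idx]]
        t = sps.ttest_ind(g1, g2, equal_var=False).statistic
        maxes.append(np.abs(t).max())
    maxes = np.array(maxes)
    return np.array([(maxes >= abs(t)).mean() for t in t_obs])


class TestTmax:
    def test_identical_samples_give_p_one(self, rng):
        a = rng.standard_normal((6, 3))
        res = tmax_permutation_test(a, a.copy(), n_perm=200, seed=0)
        np.testing.assert_array_equal(res.t, 0.0)
        np.testing.assert_array_equal(res.p, 1.0)

    def test_constant_channel_warns_p_one(self, rng):
        a = rng.standard_normal((6, 2))
        b = rng.standard_normal((6, 2))
        a[:, 1] = 5.0
        b[:, 1] = 5.0
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            res = tmax_permutation_test(a, b, n_perm=100, seed=0)
        assert res.p[1] == 1.0

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        a = rng.standard_normal((4, 2)) + np.array([1.5, 0.0])
        b = rng.standard_normal((4, 2))
        res = tmax_permutation_test(a, b, n_perm=69, seed=0)
        assert res.exact
        assert res.n_permutations == 69  # C(8,4) - 1
        np.testing.assert_allclose(res.p, brute_force_tmax_p(a, b), atol=1e-12)

    def test_detects_single_strong_channel(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = r.standard_normal((100, 21))
            b = r.standard_normal((100, 21))
            a[:, 13] += 3.0  # d = 3 on one channel
            res = tmax_permutation_test(a, b, n_perm=500, seed=seed)
            sig = res.p < 0.01
            if sig[13] and sig.sum() == 1:
                hits += 1
        assert hits >= 4

    def test_affine_invariance(self, rng):
        a = rng.standard_normal((12, 4))
        b = rng.standard_normal((10, 4)) + 0.5
        scale = np.array([2.0, 0.5, 10.0, 1.0])
        offset = np.array([-1.0, 3.0, 0.0, 100.0])
        r1 = tmax_permutation_test(a, b, n_perm=300, seed=5)
        r2 = tmax_permutation_test(a * scale + offset, b * scale + offset,
                                   n_perm=300, seed=5)
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)
        np.testing.assert_allclose(r1.t, r2.t, atol=1e-9)

    def test_swap_symmetry(self, rng):
        a = rng.standard_normal((9, 3)) + 0.8
        b = rng.standard_normal((12, 3))
        r1 = tmax_permutation_test(a, b, n_perm=400, seed=3)
        r2 = tmax_permutation_test(b, a, n_perm=400, seed=3)
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)
        np.testing.assert_allclose(r1.t, -r2.t, atol=1e-9)
        np.testing.assert_array_equal(r1.effect_sign, -r2.effect_sign)

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        a = rng.standard_normal((50, 2))
        b = rng.standard_normal((50, 2)) + np.array([5.0, 0.0])
        res = tmax_permutation_test(a, b, n_perm=200, seed=0)
        assert res.p[0] == pytest.approx(1.0 / 201.0)

    def test_too_few_epochs_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2 epochs"):
            tmax_permutation_test(rng.standard_normal((1, 3)),
                                  rng.standard_normal((5, 3)))

    def test_mismatched_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="channel set"):
            tmax_permutation_test(rng.standard_normal((5, 3)),
                                  rng.standard_normal((5, 4)))


def _bp(values: np.ndarray, condition: str) -> BandPower:
    """BandPower with the given per-epoch alpha-band values (other bands
    filled with the same draw)."""
    n_ep, n_ch = values.shape
    full = np.repeat(values[:, :, None], len(DEFAULT_BANDS), axis=2)
    return BandPower(
        values=full,
        scheme=DEFAULT_BANDS,
        channel_mask=np.ones(n_ch, dtype=bool),
        epoch_mask=np.ones(n_ep, dtype=bool),
        condition=condition,
    )


class TestCategorize:
    @pytest.fixture
    def powers(self, rng):
        """Six channels engineered to hit the taxonomy decision table.

        log10 power offsets vs baseline (speech, music):
        ch0 (+1, 0)   -> selective_speech
        ch1 (+1, +1)  -> shared
        ch2 (+1, +.5) -> preferred_speech
        ch3 (0, 0)    -> none
        ch4 (0, +1)   -> selective_music
        ch5 (-1, -1)  -> shared (deactivation)
        """
        rng = np.random.default_rng(42)
        n = 60
        base = 10 ** rng.normal(0.0, 0.1, size=(n, 6))
        speech = 10 ** (rng.normal(0.0, 0.1, size=(n, 6))
                        + np.array([1, 1, 1, 0, 0, -1]))
        music = 10 ** (rng.normal(0.0, 0.1, size=(n, 6))
                       + np.array([0, 1, 0.5, 0, 1, -1]))
        return (_bp(speech, "speech"), _bp(music, "music"),
                _bp(base, "baseline_tones"))

    def test_activation_decision_table(self, powers):
        df = categorize_channels(*powers, band="alpha", direction="activation",
                                 n_perm=300, seed=0)
        cats = df.set_index("channel")["category"].astype(str)
        assert cats[0] == "selective_speech"
        assert cats[1] == "shared"
        assert cats[2] == "preferred_speech"
        assert cats[3] == "none"
        assert cats[4] == "selective_music"
        assert cats[5] == "none"  # deactivated channel: no activation response

    def test_deactivation_decision_table(self, powers):
        df = categorize_channels(*powers, band="alpha", direction="deactivation",
                                 n_perm=300, seed=0)
        cats = df.set_index("channel")["category"].astype(str)
        assert cats[5] == "shared"
        assert cats[0] == "none"

    def test_both_directions_concatenated(self, powers):
        df = categorize_channels(*powers, band="alpha", direction="both",
                                 n_perm=300, seed=0)
        assert set(df["direction"]) == {"activation", "deactivation"}
        assert len(df) == 12

    def test_swapping_domains_swaps_labels(self, powers):
        ps, pm, pb = powers
        d1 = categorize_channels(ps, pm, pb, band="alpha",
                                 direction="activation", n_perm=300, seed=0)
        d2 = categorize_channels(pm, ps, pb, band="alpha",
                                 direction="activation", n_perm=300, seed=0)
        swap = {
            "selective_speech": "selective_music",
            "selective_music": "selective_speech",
            "preferred_speech": "preferred_music",
            "preferred_music": "preferred_speech",
        }
        expect = d1["category"].astype(str).map(lambda c: swap.get(c, c))
        assert list(d2["category"].astype(str)) == list(expect)

    def test_invalid_alpha_rejected(self, powers):
        with pytest.raises(ValueError, match="alpha"):
            categorize_channels(*powers, band="alpha", alpha=1.5)

    def test_masked_channels_excluded(self, powers):
        ps, pm, pb = powers
        ps.channel_mask[2] = False
        df = categorize_channels(ps, pm, pb, band="alpha",
                                 direction="activation", n_perm=100, seed=0)
        assert 2 not in set(df["channel"])


class TestFdrBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identity_cases(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(fdr_bh([0.2]), [0.2])
        assert fdr_bh([]).size == 0

    def test_q_dominates_p(self, rng):
        p = rng.uniform(size=50)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])
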