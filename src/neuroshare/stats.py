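"""Max-statistic (tmax) permutation testing and the response taxonomy.

The tmax method controls the familywise error rate across channels: for
each permutation of the condition labels the most extreme |t| over
channels enters the null distribution, so every channel's statistic is
compared against the distribution of the *maximum* — the test automatically
grows more conservative with more channels.

Because run lengths differ between conditions (e.g. ~115 speech vs ~116
music epochs), the test is an unpaired label permutation of the Welch
two-sample t statistic: condition labels are swapped between pooled epochs.
The permutation null is built on a canonical (sorted) arrangement of the
pooled epochs and on the smaller group size, which makes the p-values
exactly invariant under exchanging the two inputs.

The taxonomy (per channel x band x direction): a *simple effect* is a
significant difference from baseline whose sign matches the direction under
study (activation: condition > baseline; deactivation: reverse).  Writing S
and M for the speech and music simple effects and D for a significant
speech-music difference:

=========  ===  ==================================================
S and M     D   preferred toward the larger response
S and M    ~D   shared
S xor M     D   selective for the significant domain (if D favors
                it; a contradictory sign is flagged `inconsistent`)
S xor M    ~D   shared
neither     -   none (the difference is not assessed)
=========  ===  ==================================================

Tests run on log10 band power: effect sizes are defined on log power,
which is approximately Gaussian and hence matches the t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .spectral import BandPower

__all__ = [
    "TestResult",
    "tmax_permutation_test",
    "categorize_channels",
    "fdr_bh",
    "CATEGORY_ORDER",
]

CATEGORY_ORDER = (
    "none",
    "shared",
    "selective_speech",
    "selective_music",
    "preferred_speech",
    "preferred_music",
    "inconsistent",
)


@dataclass
class TestResult:
    """Outcome of one tmax permutation test over channels."""

    t: np.ndarray  # observed Welch t per channel
    p: np.ndarray  # tmax-corrected two-tailed p per channel
    effect_sign: np.ndarray  # sign of mean(a) - mean(b)
    mean_a: np.ndarray
    mean_b: np.ndarray
    n_permutations: int
    exact: bool = False

    def significant(self, alpha: float = 0.01) -> np.ndarray:
        return self.p < alpha


def _welch_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Welch t from per-group sums; zero-variance channels give t = 0."""
    ma = sum_a / n_a
    mb = sum_b / n_b
    va = (sumsq_a - n_a * ma**2) / (n_a - 1)
    vb = (sumsq_b - n_b * mb**2) / (n_b - 1)
    denom = np.sqrt(np.maximum(va, 0) / n_a + np.maximum(vb, 0) / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def tmax_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    exact: bool | None = None,
) -> TestResult:
    """Two-tailed unpaired tmax permutation test, one p per channel.

    Parameters
    ----------
    a, b : ndarray, shape (n_epochs, n_channels)
        Per-epoch values for the two conditions (same channel set).
    n_perm : int
        Monte-Carlo permutations.  When the number of distinct label
        splits ``C(n_a+n_b, min(n_a, n_b))`` does not exceed ``n_perm + 1``
        (or ``exact=True``), all splits are enumerated instead and the
        p-values are exact.
    seed : int or Generator
        Source of randomness for the Monte-Carlo draw.

    Returns
    -------
    TestResult
        ``p = (1 + #{perm : tmax_perm >= |t_obs|}) / (n_perm + 1)`` in the
        Monte-Carlo case; in the exact case the count runs over all splits
        (the observed one included), so p is never 0 in either mode.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions must share the channel set")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 epochs per condition")

    pooled = np.concatenate([a, b], axis=0)
    n = n_a + n_b
    k = min(n_a, n_b)

    sum_a = a.sum(axis=0)
    sumsq_a = (a**2).sum(axis=0)
    sum_b = b.sum(axis=0)
    sumsq_b = (b**2).sum(axis=0)
    t_obs = _welch_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b)
    zero_var = (a.var(axis=0) + b.var(axis=0)) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} channel(s) with zero pooled variance: p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )

    # canonical arrangement: permutation draws depend only on the pooled
    # multiset of epochs, not on which argument they arrived in
    order = np.lexsort(pooled.T[::-1]) if pooled.shape[1] else np.arange(n)
    canon = pooled[order]
    tot = canon.sum(axis=0)
    totsq = (canon**2).sum(axis=0)

    n_splits = comb(n, k)
    use_exact = exact if exact is not None else (n_splits <= n_perm + 1)

    # comparison threshold with a relative epsilon: the observed split is
    # re-assembled from canonical sums whose addition order differs, so an
    # exactly-equal tmax must still count as >=
    abs_t = np.abs(t_obs)
    thr = abs_t - 1e-9 * np.maximum(abs_t, 1.0)
    if use_exact:
        ge = np.zeros_like(abs_t)
        for idx in combinations(range(n), k):
            g = canon[list(idx)]
            s1 = g.sum(axis=0)
            q1 = (g**2).sum(axis=0)
            t = _welch_t(s1, q1, k, tot - s1, totsq - q1, n - k)
            ge += np.abs(t).max() >= thr
        p = ge / n_splits
        n_eff = n_splits - 1
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ge = np.zeros_like(abs_t)
        for _ in range(n_perm):
            idx = rng.permutation(n)[:k]
            g = canon[idx]
            s1 = g.sum(axis=0)
            q1 = (g**2).sum(axis=0)
            t = _welch_t(s1, q1, k, tot - s1, totsq - q1, n - k)
            ge += np.abs(t).max() >= thr
        p = (1.0 + ge) / (n_perm + 1.0)
        n_eff = n_perm

    p = np.where(zero_var, 1.0, np.clip(p, 0, 1))
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    return TestResult(
        t=t_obs,
        p=p,
        effect_sign=np.sign(mean_a - mean_b),
        mean_a=mean_a,
        mean_b=mean_b,
        n_permutations=n_eff,
        exact=bool(use_exact),
    )


def _log_power(bp: BandPower, band: str, channel_mask: np.ndarray) -> np.ndarray:
    vals = bp.band(band, retained_only=False)[bp.epoch_mask][:, channel_mask]
    return np.log10(np.maximum(vals, 1e-300))


def categorize_channels(
    power_speech: BandPower,
    power_music: BandPower,
    power_baseline: BandPower,
    band: str,
    direction: str = "activation",
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify every retained channel for one band and response direction.

    Runs three tmax permutation tests on log10 band power (speech vs
    baseline, music vs baseline, speech vs music) and applies the taxonomy
    decision table.  Channels rejected in any condition are excluded.
    ``direction="both"`` reuses the same three tests for activation and
    deactivation and returns both sets of rows (the tests do not depend on
    the direction; only the sign filters do).

    Returns a DataFrame with one row per retained channel (and direction):
    ``channel`` (index into the full channel set), ``category``, the three
    t statistics and tmax-corrected p-values, and the log-power means.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if direction not in ("activation", "deactivation", "both"):
        raise ValueError(f"unknown direction {direction!r}")

    ch_mask = (
        power_speech.channel_mask
        & power_music.channel_mask
        & power_baseline.channel_mask
    )
    ls = _log_power(power_speech, band, ch_mask)
    lm = _log_power(power_music, band, ch_mask)
    lb = _log_power(power_baseline, band, ch_mask)

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    res_sb = tmax_permutation_test(ls, lb, n_perm=n_perm, seed=rngs[0])
    res_mb = tmax_permutation_test(lm, lb, n_perm=n_perm, seed=rngs[1])
    res_sm = tmax_permutation_test(ls, lm, n_perm=n_perm, seed=rngs[2])

    directions = (
        ("activation", "deactivation") if direction == "both" else (direction,)
    )
    frames = []
    for direc in directions:
        sgn = 1.0 if direc == "activation" else -1.0
        s_sig = (res_sb.p < alpha) & (sgn * (res_sb.mean_a - res_sb.mean_b) > 0)
        m_sig = (res_mb.p < alpha) & (sgn * (res_mb.mean_a - res_mb.mean_b) > 0)
        d_sig = res_sm.p < alpha
        favors_speech = sgn * (res_sm.mean_a - res_sm.mean_b) > 0

        cats = []
        for i in range(ls.shape[1]):
            S, M, D = s_sig[i], m_sig[i], d_sig[i]
            if S and M:
                if D:
                    cats.append(
                        "preferred_speech" if favors_speech[i] else "preferred_music"
                    )
                else:
                    cats.append("shared")
            elif S or M:
                if D:
                    if (S and favors_speech[i]) or (M and not favors_speech[i]):
                        cats.append("selective_speech" if S else "selective_music")
                    else:
                        cats.append("inconsistent")
                else:
                    cats.append("shared")
            else:
                cats.append("none")

        frames.append(
            pd.DataFrame(
                {
                    "channel": np.flatnonzero(ch_mask),
                    "band": band,
                    "direction": direc,
                    "category": pd.Categorical(cats, categories=list(CATEGORY_ORDER)),
                    "t_speech": res_sb.t,
                    "p_speech": res_sb.p,
                    "t_music": res_mb.t,
                    "p_music": res_mb.p,
                    "t_diff": res_sm.t,
                    "p_diff": res_sm.p,
                    "mean_speech": res_sb.mean_a,
                    "mean_music": res_mb.mean_a,
                    "mean_baseline": res_sb.mean_b,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
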