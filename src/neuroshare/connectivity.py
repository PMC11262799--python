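"""Seed-based spectral coherence with epoch-shuffle surrogate nulls.

Magnitude-squared coherence between a seed channel and every other channel,
estimated from Hann-windowed per-epoch cross-spectra averaged over epochs:

    C(f) = |<S_xy>|^2 / (<S_xx> <S_yy>)

then averaged over the frequencies of a canonical band.  On independent
signals this estimator is biased upward by ~1/n_epochs, which is why
significance is assessed against surrogate data: shuffling the *epoch
order of the seed only* preserves each channel's spectrum exactly while
destroying cross-channel alignment at lags of one epoch or more, so the
surrogate distribution captures the estimator bias and the spectral
structure of the data.

Coherence is one-sided: only values above the surrogate null count as a
simple effect (there is no deactivation analog), and the taxonomy applied
to connections therefore has no activation/deactivation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import EpochSet
from .spectral import DEFAULT_BANDS, BandScheme
from .stats import fdr_bh

__all__ = [
    "CoherenceResult",
    "band_coherence",
    "surrogate_null",
    "coherence_difference_test",
    "categorize_connections",
    "epoch_cross_spectra",
]


@dataclass
class CoherenceResult:
    """Seed-based band coherence with its surrogate-null assessment."""

    coherence: np.ndarray  # per channel, NaN where excluded
    p: np.ndarray
    q: np.ndarray
    threshold: np.ndarray  # per-channel 1-alpha surrogate quantile
    seed_channel: int
    band: str
    condition: str = ""
    n_surrogates: int = 0


def _retained_spectra(epochs: EpochSet):
    """Hann-windowed rFFT per retained epoch x channel, and the in-band
    frequency grid."""
    x = epochs.retained()
    win = np.hanning(x.shape[-1])
    spec = np.fft.rfft(x * win, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / epochs.sample_rate)
    return spec, freqs


def epoch_cross_spectra(epochs: EpochSet, band: tuple[float, float]):
    """Per-epoch spectra restricted to a band: (spec [ep x ch x f], channel ids)."""
    spec, freqs = _retained_spectra(epochs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return spec[..., sel], np.flatnonzero(epochs.channel_mask)


def _seed_neighbors(epochs: EpochSet, seed_channel: int, radius: int = 1) -> set:
    """Channels immediately neighboring the seed on the same shaft."""
    seed_info = epochs.channels[seed_channel]
    out = set()
    for i, ch in enumerate(epochs.channels):
        if i == seed_channel:
            continue
        if (
            ch.shaft_id == seed_info.shaft_id
            and abs(ch.contact_index - seed_info.contact_index) <= radius
        ):
            out.add(i)
    return out


def _msc_from_spectra(spec: np.ndarray, seed_pos: int) -> np.ndarray:
    """Band-averaged magnitude-squared coherence of every channel with the
    seed, from per-epoch band spectra (epochs x channels x freqs)."""
    seed = spec[:, seed_pos, :]
    sxy = (spec * np.conj(seed[:, None, :])).mean(axis=0)
    sxx = (np.abs(spec) ** 2).mean(axis=0)
    syy = (np.abs(seed) ** 2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(sxy) ** 2 / (sxx * syy[None, :])
    return np.nanmean(c, axis=-1)


def band_coherence(
    epochs: EpochSet,
    seed_channel: int,
    band: tuple[float, float] | str,
    scheme: BandScheme = DEFAULT_BANDS,
    exclude_neighbors: bool = True,
) -> np.ndarray:
    """Band coherence of every channel with the seed.

    ``seed_channel`` indexes the full channel set.  Returns one value per
    full-set channel: NaN for rejected channels, the seed itself, its
    immediate same-shaft neighbors (volume-conduction guard) and
    zero-variance channels.
    """
    if isinstance(band, str):
        band = scheme.edges(band)
    if epochs.epoch_mask.sum() < 8:
        raise ValueError("need >= 8 retained epochs for a stable coherence estimate")
    if not epochs.channel_mask[seed_channel]:
        raise ValueError("seed channel is not retained")
    spec, ch_ids = epoch_cross_spectra(epochs, band)
    seed_pos = int(np.flatnonzero(ch_ids == seed_channel)[0])
    c = _msc_from_spectra(spec, seed_pos)

    zero_var = epochs.retained().var(axis=(0, 2)) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance channel(s) excluded from coherence",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.full(epochs.n_channels, np.nan)
    out[ch_ids] = np.where(zero_var, np.nan, c)
    out[seed_channel] = np.nan
    if exclude_neighbors:
        for nb in _seed_neighbors(epochs, seed_channel):
            out[nb] = np.nan
    return out


def surrogate_null(
    epochs: EpochSet,
    seed_channel: int,
    band: tuple[float, float] | str,
    n_surr: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.01,
    scheme: BandScheme = DEFAULT_BANDS,
    exclude_neighbors: bool = True,
) -> CoherenceResult:
    """Epoch-shuffle surrogate assessment of seed coherence.

    Each surrogate permutes the epoch order of the *seed* channel only
    (identity permutation excluded) and recomputes the band coherence for
    every channel.  Per channel: empirical
    ``p = (1 + #{surr >= observed}) / (n_surr + 1)``, BH q across channels,
    and the ``1 - alpha`` surrogate quantile as the genuine-connectivity
    threshold.
    """
    if isinstance(band, str):
        band = scheme.edges(band)
    n_ret = int(epochs.epoch_mask.sum())
    if n_ret < 8:
        raise ValueError("need >= 8 retained epochs")
    if n_surr < 100:
        raise ValueError("need >= 100 surrogates for a usable null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = band_coherence(epochs, seed_channel, band, scheme, exclude_neighbors)
    spec, ch_ids = epoch_cross_spectra(epochs, band)
    seed_pos = int(np.flatnonzero(ch_ids == seed_channel)[0])
    seed_spec = spec[:, seed_pos, :]
    sxx = (np.abs(spec) ** 2).mean(axis=0)
    syy = (np.abs(seed_spec) ** 2).mean(axis=0)

    null = np.empty((n_surr, epochs.n_channels))
    null.fill(np.nan)
    valid = ~np.isnan(observed)
    vpos = np.isin(ch_ids, np.flatnonzero(valid))
    for s in range(n_surr):
        perm = rng.permutation(n_ret)
        while np.array_equal(perm, np.arange(n_ret)):
            perm = rng.permutation(n_ret)
        sxy = (spec[:, vpos, :] * np.conj(seed_spec[perm][:, None, :])).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(sxy) ** 2 / (sxx[vpos] * syy[None, :])
        null[s, np.flatnonzero(valid)] = np.nanmean(c, axis=-1)

    p = np.full(epochs.n_channels, np.nan)
    thr = np.full(epochs.n_channels, np.nan)
    ge = (null >= observed[None, :]).sum(axis=0)
    p[valid] = (1.0 + ge[valid]) / (n_surr + 1.0)
    thr[valid] = np.quantile(null[:, valid], 1.0 - alpha, axis=0)
    q = np.full(epochs.n_channels, np.nan)
    q[valid] = fdr_bh(p[valid])
    return CoherenceResult(
        coherence=observed,
        p=p,
        q=q,
        threshold=thr,
        seed_channel=seed_channel,
        band=f"{band[0]}-{band[1]}",
        condition=epochs.condition,
        n_surrogates=n_surr,
    )


def coherence_difference_test(
    epochs_speech: EpochSet,
    epochs_music: EpochSet,
    seed_channel: int,
    band: tuple[float, float] | str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    scheme: BandScheme = DEFAULT_BANDS,
    exclude_neighbors: bool = True,
):
    """Permutation test of a speech-music coherence difference per channel.

    Statistic: ``C_speech - C_music``.  The null permutes condition labels
    across the pooled epochs (keeping group sizes), recomputing both
    coherences.  Two-tailed empirical p with BH q.  Returns a DataFrame
    with columns channel, c_speech, c_music, diff, p, q.
    """
    if isinstance(band, str):
        band = scheme.edges(band)
    cs = band_coherence(epochs_speech, seed_channel, band, scheme, exclude_neighbors)
    cm = band_coherence(epochs_music, seed_channel, band, scheme, exclude_neighbors)
    valid = ~np.isnan(cs) & ~np.isnan(cm)
    diff = cs - cm

    spec_s, ids_s = epoch_cross_spectra(epochs_speech, band)
    spec_m, ids_m = epoch_cross_spectra(epochs_music, band)
    if not np.array_equal(ids_s, ids_m):
        raise ValueError("conditions must share the retained channel set")
    seed_pos = int(np.flatnonzero(ids_s == seed_channel)[0])
    pooled = np.concatenate([spec_s, spec_m], axis=0)
    n_s, n_m = spec_s.shape[0], spec_m.shape[0]
    if n_s < 8 or n_m < 8:
        raise ValueError("need >= 8 retained epochs per condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # canonical epoch order + split at the smaller group size: the sampled
    # partitions (and hence p) are exactly invariant under swapping the
    # condition inputs; the two-tailed |difference| ignores group naming
    order = sorted(range(n_s + n_m), key=lambda i: pooled[i].tobytes())
    canon = pooled[order]
    k = min(n_s, n_m)
    ge = np.zeros(pooled.shape[1])
    abs_obs = np.abs(diff[ids_s])
    for _ in range(n_perm):
        perm = rng.permutation(n_s + n_m)
        d = _msc_from_spectra(canon[perm[:k]], seed_pos) - _msc_from_spectra(
            canon[perm[k:]], seed_pos
        )
        ge += np.abs(d) >= abs_obs - 1e-12
    p_band = (1.0 + ge) / (n_perm + 1.0)

    p = np.full(len(cs), np.nan)
    p[ids_s] = p_band
    p[~valid] = np.nan
    q = np.full(len(cs), np.nan)
    q[valid] = fdr_bh(p[valid])
    return pd.DataFrame(
        {
            "channel": np.flatnonzero(valid),
            "c_speech": cs[valid],
            "c_music": cm[valid],
            "diff": diff[valid],
            "p": p[valid],
            "q": q[valid],
        }
    )


def categorize_connections(
    result_speech: CoherenceResult,
    result_music: CoherenceResult,
    difference: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Apply the shared/preferred/selective taxonomy to seed connections.

    A simple effect is coherence above the surrogate null (q < alpha);
    coherence is one-sided, so there is no direction split.  The decision
    table matches the band-power taxonomy with "favoring" read from the
    sign of the coherence difference.
    """
    rows = []
    diff_by_ch = difference.set_index("channel")
    for ch in diff_by_ch.index:
        S = result_speech.q[ch] < alpha
        M = result_music.q[ch] < alpha
        D = diff_by_ch.loc[ch, "q"] < alpha
        favors_speech = diff_by_ch.loc[ch, "diff"] > 0
        if S and M:
            cat = ("preferred_speech" if favors_speech else "preferred_music") if D else "shared"
        elif S or M:
            if D:
                if (S and favors_speech) or (M and not favors_speech):
                    cat = "selective_speech" if S else "selective_music"
                else:
                    cat = "inconsistent"
            else:
                cat = "shared"
        else:
            cat = "none"
        rows.append(
            {
                "channel": int(ch),
                "c_speech": float(result_speech.coherence[ch]),
                "c_music": float(result_music.coherence[ch]),
                "q_speech": float(result_speech.q[ch]),
                "q_music": float(result_music.q[ch]),
                "q_diff": float(diff_by_ch.loc[ch, "q"]),
                "category": cat,
            }
        )
    return pd.DataFrame(rows)
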