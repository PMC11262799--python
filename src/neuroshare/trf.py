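"""Temporal response functions: stimulus features, ridge estimation,
model comparison and seed selection.

A forward TRF is a lag-resolved linear filter ``w(l)`` predicting neural
activity from a stimulus feature: ``y(t) = sum_l w(l) s(t - l)``.  Two
features are supported — the broadband cochlear envelope and its acoustic
onset edges (peakRate) — and two neural targets: low-frequency activity
(LF, 1-9 Hz band-passed broadband) and the high-frequency amplitude
(80-120 Hz, see :mod:`neuroshare.preprocess`).  Everything runs at 100 Hz
with lags from -150 to 1000 ms in 10-ms steps (116 lags).

Model fitting uses ridge regression (identity penalty, unpenalized
intercept) on the first 80% of the run; the held-out final 20% yields the
per-channel prediction accuracy (Pearson r, Fisher z-scored, parametric p,
BH-corrected q).  The split is contiguous so that temporal autocorrelation
cannot leak across it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .stats import fdr_bh

__all__ = [
    "StimulusFeature",
    "NeuralTarget",
    "TRFModel",
    "zscore",
    "erb_space",
    "cochlear_envelope",
    "peak_rate",
    "fit_trf",
    "cross_validate_lambda",
    "score_trf",
    "compare_models",
    "select_seed",
    "DEFAULT_LAMBDA_GRID",
    "lf_target",
    "hfa_target",
]

FEATURE_RATE = 100.0
DEFAULT_LAGS_MS = (-150.0, 1000.0)
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(0, 9))


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score; an (all-constant) degenerate series maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class StimulusFeature:
    """A z-scored stimulus feature series at 100 Hz."""

    kind: str  # "envelope" | "peakRate"
    series: np.ndarray
    rate: float = FEATURE_RATE
    source: str = ""


@dataclass
class NeuralTarget:
    """Per-channel neural series at 100 Hz (LF or HFa amplitude)."""

    kind: str  # "LF" | "HFa_amplitude"
    series: np.ndarray  # channels x time
    rate: float = FEATURE_RATE

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))


@dataclass
class TRFModel:
    """Fitted forward model: per-channel lag kernels plus intercepts."""

    lags_ms: np.ndarray
    weights: np.ndarray  # n_lags x n_channels
    intercept: np.ndarray
    lam: float
    feature_kind: str = ""
    target_kind: str = ""
    x_mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_lags(self) -> int:
        return len(self.lags_ms)


# ---------------------------------------------------------------------------
# stimulus features


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """Centre frequencies equally spaced on the ERB-rate scale."""
    erb = lambda f: 21.4 * np.log10(1.0 + 0.00437 * f)  # noqa: E731
    inv = lambda e: (10.0 ** (e / 21.4) - 1.0) / 0.00437  # noqa: E731
    return inv(np.linspace(erb(fmin), erb(fmax), n))


def cochlear_envelope(
    audio: np.ndarray,
    fs: float,
    n_bands: int = 32,
    fmin: float = 80.0,
    fmax: float = 8000.0,
    out_rate: float = FEATURE_RATE,
) -> np.ndarray:
    """Broadband temporal envelope via a 32-band cochlear-style filterbank.

    The waveform is decomposed into ``n_bands`` gammatone bands with
    ERB-spaced centres between ``fmin`` and ``fmax``, the magnitude of the
    analytic (Hilbert) signal is taken per band and the bands are summed.
    The summed envelope is anti-alias low-passed and downsampled to
    ``out_rate``.  Returns the *raw* (non-negative) envelope; z-score it
    (:func:`zscore`) to obtain the model feature, and feed it raw to
    :func:`peak_rate`.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if len(audio) < fs:
        raise ValueError("audio must be at least 1 s long")
    if np.allclose(audio, 0):
        warnings.warn("silent input: zero envelope", RuntimeWarning, stacklevel=2)
        n_out = int(round(len(audio) / fs * out_rate))
        return np.zeros(n_out)

    env = np.zeros_like(audio)
    for fc in erb_space(fmin, min(fmax, 0.45 * fs), n_bands):
        b, a = signal.gammatone(fc, "iir", fs=fs)
        band = signal.lfilter(b, a, audio)
        env += np.abs(signal.hilbert(band))

    sos = signal.butter(4, 0.4 * out_rate, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, env)
    down = signal.resample_poly(env, int(out_rate), int(fs))
    return np.maximum(down, 0.0)


def peak_rate(envelope: np.ndarray, rate: float = FEATURE_RATE) -> StimulusFeature:
    """Acoustic onset edges: peaks of the envelope's rate of change.

    Takes the first difference of the (raw, pre-z-scoring) envelope,
    half-wave rectifies it, and marks strict local maxima as events whose
    amplitude is the derivative value (zeros elsewhere).  The sparse series
    is then z-scored over its full length, zeros included.
    """
    env = np.asarray(envelope, dtype=float)
    d = np.diff(env, prepend=env[0])
    d = np.maximum(d, 0.0)
    events = np.zeros_like(d)
    if len(d) > 2:
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > 0)
        events[1:-1][interior] = d[1:-1][interior]
    return StimulusFeature(kind="peakRate", series=zscore(events), rate=rate)


def envelope_feature(envelope_raw: np.ndarray, source: str = "") -> StimulusFeature:
    return StimulusFeature(kind="envelope", series=zscore(envelope_raw), source=source)


# ---------------------------------------------------------------------------
# neural targets


def lf_target(data: np.ndarray, fs: float, lo: float = 1.0, hi: float = 9.0,
              out_rate: float = FEATURE_RATE) -> NeuralTarget:
    """Low-frequency target: 1-9 Hz band-pass, downsampled to 100 Hz."""
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    lf = signal.sosfiltfilt(sos, np.atleast_2d(data), axis=-1)
    down = signal.resample_poly(lf, int(out_rate), int(fs), axis=-1)
    return NeuralTarget(kind="LF", series=down, rate=out_rate)


def hfa_target(data: np.ndarray, fs: float, out_rate: float = FEATURE_RATE
               ) -> NeuralTarget:
    """High-frequency amplitude target (80-120 Hz normalized analytic
    amplitude, see preprocessing), anti-aliased and downsampled to 100 Hz."""
    from .preprocess import hfa_amplitude
    from .recording import ChannelInfo, Recording

    data = np.atleast_2d(data)
    rec = Recording(
        patient_id="_", condition="speech", sample_rate=fs, data=data,
        channels=[ChannelInfo(label=f"c{i}") for i in range(data.shape[0])],
    )
    amp = hfa_amplitude(rec).data
    sos = signal.butter(4, 0.4 * out_rate, btype="lowpass", fs=fs, output="sos")
    amp = signal.sosfiltfilt(sos, amp, axis=-1)
    down = signal.resample_poly(amp, int(out_rate), int(fs), axis=-1)
    return NeuralTarget(kind="HFa_amplitude", series=down, rate=out_rate)


# ---------------------------------------------------------------------------
# ridge TRF


def _lag_samples(rate: float, lags_ms=DEFAULT_LAGS_MS) -> np.ndarray:
    lo = int(round(lags_ms[0] / 1000.0 * rate))
    hi = int(round(lags_ms[1] / 1000.0 * rate))
    return np.arange(lo, hi + 1)


def _design_matrix(series: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Lagged copies of the feature, zero-padded at the edges.

    Column ``l`` holds ``s(t - lag_l)``; negative lags look into the
    future of the stimulus (acausal part of the kernel).
    """
    n = len(series)
    X = np.zeros((n, len(lags)))
    for j, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, j] = series[: n - lag] if lag else series
        else:
            X[:lag, j] = series[-lag:]
    return X


def fit_trf(
    feature: StimulusFeature,
    target: NeuralTarget,
    lam: float,
    lags_ms=DEFAULT_LAGS_MS,
) -> TRFModel:
    """Ridge solution of the forward model for every channel.

    Solves ``(Xc'Xc + lam*I) w = Xc'Yc`` on mean-centred data (the
    intercept is unpenalized).  ``lam = 0`` reduces to ordinary least
    squares.
    """
    if lam < 0:
        raise ValueError("ridge parameter must be >= 0")
    y = target.series
    if y.shape[1] != len(feature.series):
        raise ValueError(
            f"length mismatch: feature {len(feature.series)} vs target {y.shape[1]}"
        )
    lags = _lag_samples(feature.rate, lags_ms)
    X = _design_matrix(feature.series, lags)
    x_mean = X.mean(axis=0)
    y_mean = y.mean(axis=1)
    Xc = X - x_mean
    Yc = (y - y_mean[:, None]).T
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    W = np.linalg.solve(A, Xc.T @ Yc)
    intercept = y_mean - x_mean @ W
    return TRFModel(
        lags_ms=lags / feature.rate * 1000.0,
        weights=W,
        intercept=intercept,
        lam=lam,
        feature_kind=feature.kind,
        target_kind=target.kind,
        x_mean=x_mean,
    )


def predict(model: TRFModel, feature: StimulusFeature) -> np.ndarray:
    lags = np.round(model.lags_ms / 1000.0 * feature.rate).astype(int)
    X = _design_matrix(feature.series, lags)
    return ((X - model.x_mean) @ model.weights).T + model.intercept[:, None]


def _split(n: int, train_frac: float = 0.8) -> int:
    return int(round(n * train_frac))


def _effective_n(x: np.ndarray, y: np.ndarray, max_lag_frac: float = 0.25) -> float:
    """Bartlett effective sample size of corr(x, y) under autocorrelation.

    ``n_eff = n / (1 + 2 sum_{k>=1} rho_x(k) rho_y(k))``, truncated at
    ``max_lag_frac * n`` lags; never exceeds n nor drops below 4.
    """
    n = len(x)
    k_max = max(1, int(n * max_lag_frac))
    xz = x - x.mean()
    yz = y - y.mean()
    # FFT autocorrelations up to k_max
    m = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(xz, m)
    fy = np.fft.rfft(yz, m)
    ax = np.fft.irfft(fx * np.conj(fx))[:k_max + 1]
    ay = np.fft.irfft(fy * np.conj(fy))[:k_max + 1]
    if ax[0] <= 0 or ay[0] <= 0:
        return float(n)
    rho = (ax / ax[0]) * (ay / ay[0])
    tau = 1.0 + 2.0 * rho[1:].sum()
    return float(np.clip(n / max(tau, 1.0), 4.0, n))


def cross_validate_lambda(
    feature: StimulusFeature,
    target: NeuralTarget,
    channels=None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    train_frac: float = 0.8,
    lags_ms=DEFAULT_LAGS_MS,
) -> float:
    """Pick the ridge parameter by contiguous k-fold CV on designated channels.

    Folds partition the first ``train_frac`` span of the run; for each fold
    the model is fitted on the remaining training data and scored (Pearson
    r) on the fold, averaged over folds and channels.  Ties and an empty
    improvement favor the smallest lambda.
    """
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    y = target.series if channels is None else target.series[list(channels)]
    n_train = _split(y.shape[1], train_frac)
    bounds = np.linspace(0, n_train, n_folds + 1).astype(int)
    scores = np.full(len(grid), -np.inf)
    feat_tr = StimulusFeature(feature.kind, feature.series[:n_train], feature.rate)
    for gi, lam in enumerate(grid):
        rs = []
        for f in range(n_folds):
            lo, hi = bounds[f], bounds[f + 1]
            mask = np.ones(n_train, dtype=bool)
            mask[lo:hi] = False
            ftr = StimulusFeature(feature.kind, feat_tr.series[mask], feature.rate)
            ytr = NeuralTarget(target.kind, y[:, :n_train][:, mask], target.rate)
            model = fit_trf(ftr, ytr, lam, lags_ms)
            fva = StimulusFeature(feature.kind, feat_tr.series[lo:hi], feature.rate)
            pred = predict(model, fva)
            obs = y[:, lo:hi]
            for c in range(obs.shape[0]):
                if pred[c].std() > 0 and obs[c].std() > 0:
                    rs.append(np.corrcoef(pred[c], obs[c])[0, 1])
        if rs:
            scores[gi] = float(np.mean(rs))
    if not np.isfinite(scores).any():
        raise ValueError("validation correlation undefined for every lambda")
    # near-ties resolve toward the smallest lambda (validation r differences
    # below 1e-6 are numerically meaningless)
    best = scores.max()
    order = np.argsort(grid)
    for gi in order:
        if scores[gi] >= best - 1e-6:
            return grid[int(gi)]
    return grid[int(np.argmax(scores))]  # pragma: no cover


def score_trf(
    feature: StimulusFeature,
    target: NeuralTarget,
    lam: float,
    train_frac: float = 0.8,
    lags_ms=DEFAULT_LAGS_MS,
) -> pd.DataFrame:
    """Fit on the first 80%, score the held-out final 20%.

    Returns per-channel Pearson r, Fisher z (= atanh r, capped),
    a parametric two-sided p from the t transform of r, and BH q across
    channels.  Zero-variance predictions are flagged with r = 0, p = 1.

    Both the prediction and the neural target are strongly autocorrelated
    (band-limited) series, so the nominal holdout length wildly overstates
    the degrees of freedom of the correlation.  The p-value therefore uses
    the Bartlett effective sample size ``n_eff = n / (1 + 2 sum_k
    rho_x(k) rho_y(k))``, which keeps the null calibrated for smooth
    signals and reduces to the nominal n for white series.
    """
    n = target.series.shape[1]
    n_train = _split(n, train_frac)
    ftr = StimulusFeature(feature.kind, feature.series[:n_train], feature.rate)
    ytr = NeuralTarget(target.kind, target.series[:, :n_train], target.rate)
    model = fit_trf(ftr, ytr, lam, lags_ms)
    fho = StimulusFeature(feature.kind, feature.series[n_train:], feature.rate)
    pred = predict(model, fho)
    obs = target.series[:, n_train:]
    n_ho = obs.shape[1]

    rows = []
    for c in range(obs.shape[0]):
        degenerate = pred[c].std() == 0 or obs[c].std() == 0
        r = 0.0 if degenerate else float(np.corrcoef(pred[c], obs[c])[0, 1])
        r = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        if degenerate:
            p = 1.0
        else:
            n_eff = _effective_n(pred[c], obs[c])
            df = max(n_eff - 2.0, 2.0)
            tstat = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
            p = float(2 * sps.t.sf(abs(tstat), df=df))
        rows.append(
            {"channel": c, "r": r, "fisher_z": float(np.arctanh(r)), "p": p,
             "degenerate": degenerate}
        )
    df = pd.DataFrame(rows)
    df["q"] = fdr_bh(df["p"].to_numpy())
    df.attrs["model"] = model
    return df


# ---------------------------------------------------------------------------
# model comparison and seed selection


def significant_fraction(
    scores_speech: pd.DataFrame, scores_music: pd.DataFrame, alpha: float = 0.01
) -> float:
    """% of channels significantly encoding speech and/or music (union)."""
    sig = (scores_speech["q"] < alpha).to_numpy() | (
        scores_music["q"] < alpha
    ).to_numpy()
    return 100.0 * sig.mean()


def compare_models(percentages: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Group-level four-model comparison on per-patient % significant channels.

    ``percentages`` has one row per patient and one column per model.  The
    winner is the model capturing the largest mean percentage of channels;
    every other model is compared to it with a Wilcoxon signed-rank test
    across patients and the pairwise p-values are BH-corrected.  The result
    is ``decisive`` only when all pairwise q < ``alpha``; models not
    separated from the winner are listed under ``ties``.  With all-zero
    percentages no winner is declared.
    """
    if percentages.shape[0] < 6:
        warnings.warn(
            "fewer than 6 patients: signed-rank comparison is weakly powered",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.allclose(percentages.to_numpy(), 0):
        return {"winner": None, "decisive": False, "ties": [],
                "pairwise": pd.DataFrame(), "means": percentages.mean()}
    means = percentages.mean().sort_values(ascending=False)
    best = means.index[0]
    rows = []
    for other in percentages.columns:
        if other == best:
            continue
        diff = percentages[best].to_numpy() - percentages[other].to_numpy()
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(diff, zero_method="zsplit")
        rows.append({"winner": best, "alternative": other,
                     "wilcoxon_stat": float(stat), "p": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = fdr_bh(pairwise["p"].to_numpy())
    decisive = bool((pairwise["q"] < alpha).all())
    ties = pairwise.loc[pairwise["q"] >= alpha, "alternative"].tolist()
    return {
        "winner": best,
        "decisive": decisive,
        "ties": ties,
        "pairwise": pairwise,
        "means": means,
    }


def select_seed(
    scores_speech: pd.DataFrame,
    scores_music: pd.DataFrame,
    alpha: float = 0.01,
) -> int | None:
    """Best-encoding channel: argmax of mean(r_speech, r_music) among
    channels significant (q < alpha) in at least one domain.

    Returns None (patient excluded) when no channel qualifies.  Ties break
    toward the lower channel index.
    """
    mean_r = (scores_speech["r"].to_numpy() + scores_music["r"].to_numpy()) / 2.0
    eligible = (scores_speech["q"] < alpha).to_numpy() | (
        scores_music["q"] < alpha
    ).to_numpy()
    if not eligible.any():
        return None
    idx = np.flatnonzero(eligible)
    best = idx[np.argmax(mean_r[idx])]
    return int(scores_speech["channel"].iloc[best])
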