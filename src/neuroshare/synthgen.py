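"""Synthetic multi-patient sEEG cohorts with known ground truth.

Every downstream stage of the pipeline (spectral classification, TRF
encoding, seed-based coherence, prevalence aggregation) can be exercised
and *verified* on cohorts produced here, because the generator records the
exact per-channel settings it realized (:class:`GroundTruth`).

Signal model per channel and run
--------------------------------
``x(t) = background + oscillations + TRF response + artifacts`` where

* background is 1/f noise (power spectral exponent ``chi``, default 1,
  flattened below 0.5 Hz), std ``bg_std`` microvolts;
* oscillations are narrowband-filtered Gaussian noise (not sinusoids, so
  coherence/power statistics behave like field data) whose power per
  condition realizes the requested shared / preferred / selective /
  none taxonomy at effect size ``d``;
* the TRF response is a known lag kernel convolved with the stimulus
  feature (envelope or peakRate), scaled to a requested SNR against the
  1-9 Hz low-frequency background;
* artifact channels have their variance inflated x50 and artifact epochs
  receive a transient x30-amplitude burst, making them unambiguous for
  the 2xIQR detectors.

Effect sizes are defined on per-epoch *log* band power (mean shift over
pooled SD), the scale on which the t-based tests operate.  The generator
converts ``d`` into a band-power multiplier ``exp(d * sigma_b)`` using a
one-off internal calibration of the log-power SD ``sigma_b`` under pure
background (fixed internal seed, so amplitudes do not depend on the cohort
seed).

Coupled channels share a band-limited component with a designated seed
channel.  With mixing weight ``kappa`` and an oscillation-to-background
power ratio ``gamma`` in the band (both channels), the expected
magnitude-squared coherence is ``kappa^2 * (gamma / (1 + gamma))^2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .recording import ChannelInfo, Recording
from .spectral import DEFAULT_BANDS, BandScheme

__all__ = [
    "CategoryEffect",
    "TRFChannelSpec",
    "Coupling",
    "ArtifactSpec",
    "CohortConfig",
    "GroundTruth",
    "Stimulus",
    "generate_stimulus",
    "generate_cohort",
    "iter_cohort",
    "default_trf_kernel",
    "CATEGORIES",
]

CATEGORIES = (
    "none",
    "shared",
    "selective_speech",
    "selective_music",
    "preferred_speech",
    "preferred_music",
)

#: duration (s) of the speech / music / tone-baseline runs emulated by default
DEFAULT_RUN_DURATIONS = {"speech": 577.0, "music": 580.0, "baseline_tones": 150.0}

_EVENT_RATES = {"speech": 4.5, "music": 2.0}
_CAL_SEED = 0x5EED  # internal calibration seed, independent of cohort seed


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class CategoryEffect:
    """Ground-truth taxonomy assignment for one channel x band."""

    category: str
    direction: str = "activation"  # or "deactivation"
    d: float = 1.5

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.direction not in ("activation", "deactivation"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.d) or self.d < 0:
            raise ValueError("effect size d must be finite and >= 0")


@dataclass(frozen=True)
class TRFChannelSpec:
    """A channel carrying a stimulus-locked response.

    ``kernel`` is the lag kernel sampled at 100 Hz (lag 0 first);
    ``feature`` selects what it convolves (``envelope`` or ``peakRate``);
    ``snr_db`` is the response-to-background power ratio inside the 1-9 Hz
    low-frequency band.
    """

    kernel: tuple[float, ...]
    feature: str = "peakRate"
    snr_db: float = 0.0

    def __post_init__(self) -> None:
        if self.feature not in ("envelope", "peakRate"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite")


@dataclass(frozen=True)
class Coupling:
    """Band-limited coupling of one channel to a seed channel."""

    seed_channel: int
    kappa_speech: float = 0.0
    kappa_music: float = 0.0
    power_ratio: float = 10.0  # oscillation-to-background PSD ratio in band

    def __post_init__(self) -> None:
        for k in (self.kappa_speech, self.kappa_music):
            if not 0.0 <= k <= 1.0:
                raise ValueError("kappa must lie in [0, 1]")
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    channel_fraction: float = 0.0
    epoch_fraction: float = 0.0
    channel_var_factor: float = 50.0
    epoch_burst_factor: float = 30.0


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    The same category / coupling / TRF maps apply to every patient (with
    independent noise realizations); channel indices refer to positions in
    ``0..channels_per_patient-1``.
    """

    n_patients: int = 2
    channels_per_patient: int = 16
    sample_rate: float = 500.0
    run_durations: dict = field(default_factory=lambda: dict(DEFAULT_RUN_DURATIONS))
    band_scheme: BandScheme = DEFAULT_BANDS
    category_map: dict = field(default_factory=dict)  # (ch, band) -> CategoryEffect
    trf_channels: dict = field(default_factory=dict)  # ch -> TRFChannelSpec
    coupling_map: dict = field(default_factory=dict)  # (ch, band) -> Coupling
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    region_labels: list = field(default_factory=list)  # per channel
    channels_per_shaft: int = 8
    bg_std: float = 10.0  # microvolts
    bg_std_spread: float = 0.25  # lognormal sigma of per-channel gain
    bg_exponent: float = 1.0
    epoch_length: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.region_labels:
            self.region_labels = [
                f"region_{i % 4}" for i in range(self.channels_per_patient)
            ]
        if len(self.region_labels) != self.channels_per_patient:
            raise ValueError("need exactly one region label per channel")
        for dur in self.run_durations.values():
            if dur <= self.epoch_length:
                raise ValueError("run durations must exceed the epoch length")
        names = set(self.band_scheme.names)
        for (ch, band) in list(self.category_map) + list(self.coupling_map):
            if not 0 <= ch < self.channels_per_patient:
                raise ValueError(f"map references unknown channel {ch}")
            if band not in names:
                raise ValueError(f"map references unknown band {band!r}")
        for ch in self.trf_channels:
            if not 0 <= ch < self.channels_per_patient:
                raise ValueError(f"trf map references unknown channel {ch}")
        for (ch, band), coup in self.coupling_map.items():
            if not 0 <= coup.seed_channel < self.channels_per_patient:
                raise ValueError("coupling seed channel out of range")
            if (ch, band) in self.category_map:
                warnings.warn(
                    f"channel {ch} band {band} has both a category effect and a "
                    "coupling; band power will reflect their sum",
                    RuntimeWarning,
                    stacklevel=2,
                )


@dataclass
class GroundTruth:
    """Realized generative settings: the recovery-testing oracle."""

    config: CohortConfig
    calibration: dict  # per band: mean/log-SD of background band power, etc.
    artifact_channels: dict = field(default_factory=dict)  # patient -> [ch]
    artifact_epochs: dict = field(default_factory=dict)  # (patient, cond) -> [ep]

    def expected_category(self, channel: int, band: str) -> CategoryEffect:
        return self.config.category_map.get(
            (channel, band), CategoryEffect("none", "activation", 0.0)
        )

    def category_frame(self):
        """Long-format ground-truth table (one row per channel x band)."""
        import pandas as pd

        rows = []
        for p in range(self.config.n_patients):
            for ch in range(self.config.channels_per_patient):
                for band in self.config.band_scheme.names:
                    eff = self.expected_category(ch, band)
                    rows.append(
                        {
                            "patient": f"P{p:02d}",
                            "channel": ch,
                            "band": band,
                            "category": eff.category,
                            "direction": eff.direction,
                            "d": eff.d,
                        }
                    )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, BandScheme):
                return list(o.bands)
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        payload = {
            "category_map": {
                f"{ch}:{band}": asdict(eff)
                for (ch, band), eff in self.config.category_map.items()
            },
            "trf_channels": {
                str(ch): asdict(s) for ch, s in self.config.trf_channels.items()
            },
            "coupling_map": {
                f"{ch}:{band}": asdict(c)
                for (ch, band), c in self.config.coupling_map.items()
            },
            "artifact_channels": self.artifact_channels,
            "artifact_epochs": {f"{p}:{c}": v for (p, c), v in self.artifact_epochs.items()},
            "calibration": self.calibration,
            "rng_seed": self.config.rng_seed,
        }
        return json.dumps(payload, default=_default, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stimuli


@dataclass
class Stimulus:
    domain: str
    duration: float
    env_rate: float
    envelope: np.ndarray  # reference envelope at env_rate, non-negative
    audio_rate: float = 44100.0
    waveform: np.ndarray | None = None  # amplitude-modulated noise carrier

    def save_wav(self, path) -> None:
        from scipy.io import wavfile

        if self.waveform is None:
            raise ValueError("stimulus was generated without audio")
        w = self.waveform / max(1e-12, np.abs(self.waveform).max())
        wavfile.write(path, int(self.audio_rate), (w * 32000).astype(np.int16))


def generate_stimulus(
    duration: float,
    domain: str = "speech",
    seed: int = 0,
    event_rate: float | None = None,
    env_rate: float = 100.0,
    audio_rate: float = 44100.0,
    include_audio: bool = False,
) -> Stimulus:
    """Amplitude-modulated noise with a quasi-periodic smoothed-pulse envelope.

    The returned reference envelope (at ``env_rate``) is the exact modulator
    of the noise carrier.  Event rates default to 4.5 Hz for speech-like and
    2 Hz for music-like stimuli, putting the envelope modulation-spectrum
    peak below ~8 Hz with speech modulating faster than music.  With
    ``event_rate=0`` the envelope is constant (no events, hence no peakRate
    events downstream).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 10:
        warnings.warn("stimulus shorter than 10 s", RuntimeWarning, stacklevel=2)
    if event_rate is None:
        event_rate = _EVENT_RATES.get(domain, 3.0)
    rng = np.random.default_rng(seed)
    n = int(round(duration * env_rate))
    env = np.zeros(n)
    if event_rate > 0:
        # events vary in amplitude AND duration, like syllables / notes: a
        # short loud event has a sharper onset edge than a long soft one, so
        # the envelope and its onset-edge (peakRate) series carry genuinely
        # different amplitude sequences
        mean_iv = 1.0 / event_rate
        t = rng.uniform(0, mean_iv)
        while t < duration:
            amp = rng.uniform(0.5, 1.0)
            half = max(2, int(round(rng.uniform(0.25, 0.6) * mean_iv * env_rate)))
            win = np.hanning(2 * half + 1) * amp
            i0 = int(t * env_rate)
            hi = min(n, i0 + len(win))
            if i0 < n:
                env[i0:hi] += win[: hi - i0]
            t += max(0.15 * mean_iv, rng.normal(mean_iv, 0.15 * mean_iv))
        env = env / max(env.max(), 1e-12)
        env = 0.05 + 0.95 * env
    else:
        env = np.ones(n)

    waveform = None
    if include_audio:
        n_a = int(round(duration * audio_rate))
        carrier = rng.standard_normal(n_a).astype(np.float32)
        t_a = np.arange(n_a) / audio_rate
        mod = np.interp(t_a, np.arange(n) / env_rate, env).astype(np.float32)
        waveform = carrier * mod
    return Stimulus(
        domain=domain,
        duration=duration,
        env_rate=env_rate,
        envelope=env,
        audio_rate=audio_rate,
        waveform=waveform,
    )


def random_category_map(
    n_channels: int,
    bands,
    seed: int = 0,
    d: float = 1.5,
    p_none: float = 0.55,
) -> dict:
    """Draw a random taxonomy assignment for every channel x band.

    Non-none categories are equally likely among shared and the four
    selective/preferred labels; the direction is a fair coin.  Used to
    build recovery-testing cohorts with known ground truth.
    """
    rng = np.random.default_rng(seed)
    effects = [c for c in CATEGORIES if c != "none"]
    out = {}
    for ch in range(n_channels):
        for band in bands:
            if rng.random() < p_none:
                continue
            cat = effects[rng.integers(len(effects))]
            direction = "activation" if rng.random() < 0.5 else "deactivation"
            out[(ch, band)] = CategoryEffect(cat, direction, d)
    return out


def default_trf_kernel(env_rate: float = 100.0) -> np.ndarray:
    """Smooth biphasic lag kernel (~0-400 ms), energy mostly below 8 Hz."""
    t = np.arange(int(0.4 * env_rate)) / env_rate
    k = np.exp(-(((t - 0.10) / 0.04) ** 2)) - 0.6 * np.exp(
        -(((t - 0.22) / 0.06) ** 2)
    )
    return k


# ---------------------------------------------------------------------------
# noise primitives


def _expected_std(gain: np.ndarray, n: int) -> float:
    """Expected std of irfft(rfft(white) * gain) for unit-variance white
    noise; normalizing by this (not the realized std) preserves natural
    channel-to-channel variance fluctuations."""
    g2 = gain**2
    total = g2[0] + 2.0 * g2[1:-1].sum() + (g2[-1] if n % 2 == 0 else 2.0 * g2[-1])
    return float(np.sqrt(total / n))


def _one_over_f(rng: np.random.Generator, n: int, fs: float, chi: float, std: float,
                f_lo: float = 0.5) -> np.ndarray:
    """1/f^chi Gaussian noise, spectrum flattened below ``f_lo``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(f)
    nz = f > 0
    gain[nz] = np.maximum(f[nz], f_lo) ** (-chi / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n)
    return x * (std / _expected_std(gain, n))


def _narrowband(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
                ) -> np.ndarray:
    """Unit-variance (in expectation) narrowband Gaussian noise in [lo, hi]
    Hz with raised-cosine tapered edges."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    taper = 0.1 * (hi - lo)
    gain = np.clip((f - (lo - taper)) / taper, 0, 1) * np.clip(
        ((hi + taper) - f) / taper, 0, 1
    )
    x = np.fft.irfft(spec * gain, n=n)
    s = _expected_std(gain, n)
    return x / s if s > 0 else x


# ---------------------------------------------------------------------------
# calibration

_CAL_CACHE: dict = {}


def _calibrate(config: CohortConfig, n_epochs: int = 60) -> dict:
    """Per-band background statistics under the configured 1/f model.

    Simulates ``n_epochs`` background epochs for one channel (fixed internal
    seed) and measures, per band: the mean Welch band power ``mu_bg``, the SD
    of per-epoch natural-log band power ``sigma_log``, and the mean band
    power of a unit-variance narrowband oscillation ``unit_osc_power``.
    Also measures the background variance inside the 1-9 Hz LF band (for
    TRF SNR scaling).  Cached on the parameters that matter.
    """
    key = (
        config.sample_rate,
        config.bg_std,
        config.bg_exponent,
        config.epoch_length,
        config.band_scheme.bands,
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    from .preprocess import epoch as _epoch
    from .spectral import band_power as _band_power

    fs = config.sample_rate
    rng = np.random.default_rng(_CAL_SEED)
    n = int(round(n_epochs * config.epoch_length * fs))
    bg = _one_over_f(rng, n, fs, config.bg_exponent, config.bg_std)
    oscs = [
        _narrowband(rng, n, fs, lo, hi) for _, lo, hi in config.band_scheme.bands
    ]
    rec = Recording(
        patient_id="cal",
        condition="baseline_tones",
        sample_rate=fs,
        data=np.vstack([bg] + oscs),
        channels=[ChannelInfo(label=f"c{i}") for i in range(1 + len(oscs))],
    )
    bp = _band_power(_epoch(rec, config.epoch_length), config.band_scheme)
    vals = bp.values  # epochs x channels x bands
    cal: dict = {"bands": {}, "lf_band": (1.0, 9.0)}
    for k, name in enumerate(config.band_scheme.names):
        bgp = vals[:, 0, k]
        osc = vals[:, 1 + k, k]
        cal["bands"][name] = {
            "mu_bg": float(bgp.mean()),
            "var_bg": float(bgp.var(ddof=1)),
            "sigma_log": float(np.log(bgp).std(ddof=1)),
            "unit_osc_power": float(osc.mean()),
            "unit_osc_var": float(osc.var(ddof=1)),
        }
    sos = signal.butter(4, (1.0, 9.0), btype="bandpass", fs=fs, output="sos")
    cal["lf_bg_var"] = float(signal.sosfiltfilt(sos, bg).var())
    _CAL_CACHE[key] = cal
    return cal


# ---------------------------------------------------------------------------
# cohort generation


def _power_for_shift(d: float, bcal: dict, n_iter: int = 8) -> float:
    """Oscillation band power realizing a log shift of d pooled SDs.

    Adding an oscillation raises mean band power but *shrinks* the relative
    (log) fluctuation, so the pooled SD between the effect run and baseline
    is smaller than the baseline-only sigma.  Solve
    ``ln(1 + P/mu) = d * sqrt((sigma_bg^2 + sigma_+(P)^2) / 2)`` by fixed
    point, with ``sigma_+(P)`` from the delta-method log-SD of (background +
    oscillation) band power.
    """
    mu, var_bg = bcal["mu_bg"], bcal["var_bg"]
    sigma_bg = bcal["sigma_log"]
    u_mean, u_var = bcal["unit_osc_power"], bcal["unit_osc_var"]
    if d <= 0:
        return 0.0
    P = mu * (np.exp(d * sigma_bg) - 1.0)
    for _ in range(n_iter):
        var_plus = var_bg + (P / u_mean) ** 2 * u_var
        sigma_plus = np.sqrt(var_plus) / (mu + P)
        sigma_pool = np.sqrt((sigma_bg**2 + sigma_plus**2) / 2.0)
        P = mu * (np.exp(d * sigma_pool) - 1.0)
    return float(P)


def _osc_power_per_condition(eff: CategoryEffect, bcal: dict) -> dict:
    """Added band power (same units as mu_bg) per run realizing ``eff``.

    Activation: responsive runs gain power so that log band power rises by
    ``d`` pooled SDs (the weaker domain of a preferred pair by ``d/2``).
    Deactivation: the baseline run carries the oscillation and responsive
    runs lose it, mirroring the same log shifts downward.
    """
    full = _power_for_shift(eff.d, bcal)
    half = _power_for_shift(eff.d / 2.0, bcal)
    cat = eff.category
    if cat == "none" or eff.d == 0:
        return {"speech": 0.0, "music": 0.0, "baseline": 0.0}
    if eff.direction == "activation":
        base = 0.0
        sp, mu = {
            "shared": (full, full),
            "selective_speech": (full, 0.0),
            "selective_music": (0.0, full),
            "preferred_speech": (full, half),
            "preferred_music": (half, full),
        }[cat]
    else:  # deactivation: baseline holds the oscillation
        base = full
        sp, mu = {
            "shared": (0.0, 0.0),
            "selective_speech": (0.0, full),
            "selective_music": (full, 0.0),
            "preferred_speech": (0.0, half),
            "preferred_music": (half, 0.0),
        }[cat]
    return {"speech": sp, "music": mu, "baseline": base}


def _feature_series(stim: Stimulus, kind: str) -> np.ndarray:
    """Z-scored feature (envelope or peakRate) at the stimulus env_rate."""
    from . import trf as _trf

    if kind == "envelope":
        return _trf.zscore(stim.envelope)
    return _trf.peak_rate(stim.envelope).series


def _patient_recordings(
    config: CohortConfig,
    patient: int,
    stimuli: dict,
    cal: dict,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> dict:
    fs = config.sample_rate
    n_ch = config.channels_per_patient
    pid = f"P{patient:02d}"
    channels = [
        ChannelInfo(
            label=f"{pid}_ch{c:03d}",
            region=config.region_labels[c],
            hemisphere="L",
            shaft_id=f"S{c // config.channels_per_shaft}",
            contact_index=c % config.channels_per_shaft,
        )
        for c in range(n_ch)
    ]

    spec = config.artifact_spec
    n_bad_ch = int(spec.channel_fraction * n_ch)
    bad_channels = sorted(
        rng.choice(n_ch, size=n_bad_ch, replace=False).tolist()
    ) if n_bad_ch else []
    truth.artifact_channels[pid] = bad_channels

    # per-channel background level (lognormal): electrodes sit at different
    # depths/regions, so absolute signal scale varies across channels; this
    # also gives the IQR-based artifact rule a realistic spread to work with
    gains = (
        rng.lognormal(0.0, config.bg_std_spread, size=n_ch)
        if config.bg_std_spread > 0
        else np.ones(n_ch)
    )

    recordings = {}
    for condition, duration in config.run_durations.items():
        n = int(round(duration * fs))
        cond_key = "baseline" if condition.startswith("baseline") else condition
        data = np.empty((n_ch, n), dtype=np.float64)
        for c in range(n_ch):
            data[c] = _one_over_f(rng, n, fs, config.bg_exponent,
                                  config.bg_std * gains[c])

        # taxonomy oscillations (independent across channels and runs);
        # powers scale with the channel's own background level so the
        # log-power shift is gain-invariant
        for (ch, band), eff in config.category_map.items():
            lo, hi = config.band_scheme.edges(band)
            bcal = cal["bands"][band]
            power = _osc_power_per_condition(eff, bcal)
            p = power[cond_key]
            if p > 0:
                amp = gains[ch] * np.sqrt(p / bcal["unit_osc_power"])
                data[ch] += amp * _narrowband(rng, n, fs, lo, hi)

        # seed-coupled oscillations (speech/music runs only)
        if cond_key != "baseline" and config.coupling_map:
            seed_components: dict = {}
            for (ch, band), coup in config.coupling_map.items():
                lo, hi = config.band_scheme.edges(band)
                bcal = cal["bands"][band]
                osc_power = coup.power_ratio * bcal["mu_bg"]
                amp_unit = np.sqrt(osc_power / bcal["unit_osc_power"])
                skey = (coup.seed_channel, band)
                if skey not in seed_components:
                    z = _narrowband(rng, n, fs, lo, hi)
                    seed_components[skey] = z
                    data[coup.seed_channel] += gains[coup.seed_channel] * amp_unit * z
                z = seed_components[skey]
                kappa = coup.kappa_speech if cond_key == "speech" else coup.kappa_music
                w = _narrowband(rng, n, fs, lo, hi)
                data[ch] += gains[ch] * amp_unit * (
                    kappa * z + np.sqrt(1.0 - kappa**2) * w
                )

        # stimulus-locked TRF responses (speech/music runs only)
        if cond_key != "baseline" and config.trf_channels:
            stim = stimuli[condition]
            for ch, tspec in config.trf_channels.items():
                feat = _feature_series(stim, tspec.feature)
                kern = np.asarray(tspec.kernel, dtype=float)
                resp = np.convolve(feat, kern)[: len(feat)]
                up = int(round(fs / stim.env_rate))
                resp_fs = signal.resample_poly(resp, up, 1)[:n]
                if len(resp_fs) < n:
                    resp_fs = np.pad(resp_fs, (0, n - len(resp_fs)))
                sos = signal.butter(4, cal["lf_band"], btype="bandpass", fs=fs,
                                    output="sos")
                v_lf = signal.sosfiltfilt(sos, resp_fs).var()
                target = (
                    10.0 ** (tspec.snr_db / 10.0) * cal["lf_bg_var"] * gains[ch] ** 2
                )
                if v_lf > 0:
                    data[ch] += np.sqrt(target / v_lf) * resp_fs

        # artifacts last: inflated channels, burst epochs hitting every
        # channel at once (movement-like; this is what the summed-amplitude
        # epoch statistic is designed to catch)
        for ch in bad_channels:
            data[ch] *= np.sqrt(spec.channel_var_factor)
        n_ep = int(duration // config.epoch_length)
        n_bad_ep = int(spec.epoch_fraction * n_ep)
        bad_eps = sorted(
            rng.choice(n_ep, size=n_bad_ep, replace=False).tolist()
        ) if n_bad_ep else []
        truth.artifact_epochs[(pid, condition)] = bad_eps
        ep_samp = int(round(config.epoch_length * fs))
        burst_len = int(round(0.5 * fs))
        burst = np.hanning(burst_len)
        ch_std = data.std(axis=1)
        for ep in bad_eps:
            start = ep * ep_samp + (ep_samp - burst_len) // 2
            data[:, start : start + burst_len] += (
                spec.epoch_burst_factor * ch_std[:, None] * burst[None, :]
            )

        recordings[condition] = Recording(
            patient_id=pid,
            condition=condition,
            sample_rate=fs,
            data=data,
            channels=channels,
        )
    return recordings


def iter_cohort(config: CohortConfig):
    """Yield ``(patient_id, {condition: Recording})`` lazily (memory-light).

    The shared :class:`GroundTruth` is available as the generator's
    ``.truth`` attribute trick is avoided: use :func:`generate_cohort` when
    the whole cohort fits in memory, or call :func:`make_truth` and pass it
    in explicitly.
    """
    truth = make_truth(config)
    ss = np.random.SeedSequence(config.rng_seed)
    stim_ss, *patient_ss = ss.spawn(1 + config.n_patients)
    stimuli = _make_stimuli(config, stim_ss)
    for p in range(config.n_patients):
        rng = np.random.default_rng(patient_ss[p])
        recs = _patient_recordings(config, p, stimuli, truth.calibration_full, rng, truth)
        yield f"P{p:02d}", recs, truth, stimuli


def make_truth(config: CohortConfig) -> GroundTruth:
    cal = _calibrate(config)
    gt = GroundTruth(config=config, calibration={
        "sigma_log": {b: cal["bands"][b]["sigma_log"] for b in config.band_scheme.names},
        "mu_bg": {b: cal["bands"][b]["mu_bg"] for b in config.band_scheme.names},
        "lf_bg_var": cal["lf_bg_var"],
    })
    gt.calibration_full = cal  # full table, kept off the serialized surface
    return gt


def _make_stimuli(config: CohortConfig, stim_ss) -> dict:
    rngs = stim_ss.generate_state(2)
    stimuli = {}
    for i, cond in enumerate(("speech", "music")):
        if cond in config.run_durations:
            stimuli[cond] = generate_stimulus(
                config.run_durations[cond],
                domain=cond,
                seed=int(rngs[i] % (2**31)),
            )
    return stimuli


def generate_cohort(config: CohortConfig):
    """Materialize the full cohort.

    Returns ``(recordings, truth, stimuli)`` where ``recordings`` maps
    ``(patient_id, condition) -> Recording``.  Bit-identical for identical
    configs (same ``rng_seed``); distinct seeds give distinct realizations.
    """
    recordings = {}
    truth = None
    stimuli = None
    for pid, recs, truth, stimuli in iter_cohort(config):
        for cond, rec in recs.items():
            recordings[(pid, cond)] = rec
    return recordings, truth, stimuli


# ---------------------------------------------------------------------------
# persistence


def save_cohort(recordings: dict, truth: GroundTruth, out_dir, stimuli: dict | None = None
                ) -> None:
    """Write recordings as HDF5 (one file per patient x condition), the
    ground-truth manifest as JSON, and stimuli as 16-bit 44.1-kHz WAV."""
    import pathlib

    import h5py

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (pid, cond), rec in recordings.items():
        with h5py.File(out / f"{pid}_{cond}.h5", "w") as f:
            f.create_dataset("data", data=rec.data.astype(np.float32),
                             compression="gzip")
            f.attrs["patient_id"] = pid
            f.attrs["condition"] = cond
            f.attrs["sample_rate"] = rec.sample_rate
            f.create_dataset(
                "channel_labels",
                data=np.array([c.label for c in rec.channels], dtype="S"),
            )
            f.create_dataset(
                "regions", data=np.array([c.region for c in rec.channels], dtype="S")
            )
    (out / "ground_truth.json").write_text(truth.to_json())
    if stimuli:
        for cond, stim in stimuli.items():
            if stim.waveform is not None:
                stim.save_wav(out / f"stimulus_{cond}.wav")
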