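"""Re-referencing, high-frequency-amplitude extraction, epoching and
IQR-based artifact rejection for stereotactic EEG.

The artifact rules follow the robust "centre + 2 x IQR" reading: a channel
(or epoch) is rejected when its statistic exceeds ``median + 2*IQR`` of the
statistics across channels (epochs).  The IQR serves as a non-parametric
spread estimate, the median as a robust centre.

All band-pass filtering here is zero-phase (forward-backward Butterworth),
so the extracted amplitude traces have no group delay relative to the
broadband signal.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.stats import iqr as _iqr

from .recording import ChannelInfo, EpochSet, Recording

__all__ = [
    "bipolar_rereference",
    "hfa_amplitude",
    "detect_artifact_channels",
    "epoch",
    "detect_artifact_epochs",
    "notch_line_noise",
    "HFA_SUBBANDS",
]

#: Four 10-Hz-wide sub-bands spanning the 80-120 Hz high-frequency range.
HFA_SUBBANDS = ((80.0, 90.0), (90.0, 100.0), (100.0, 110.0), (110.0, 120.0))


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    return signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def bipolar_rereference(recording: Recording) -> Recording:
    """Difference adjacent same-shaft contacts into virtual bipolar channels.

    Contacts are ordered by ``contact_index`` within each shaft; each output
    channel is ``contact[i] - contact[i+1]`` with midpoint-style metadata
    (label ``"a-b"``).  A shaft with a single contact contributes nothing
    (warning).  Common-mode signal shared by all contacts of a shaft cancels
    exactly.
    """
    by_shaft: dict[str, list[int]] = {}
    for i, ch in enumerate(recording.channels):
        by_shaft.setdefault(ch.shaft_id, []).append(i)

    rows: list[np.ndarray] = []
    infos: list[ChannelInfo] = []
    for shaft, idxs in by_shaft.items():
        idxs = sorted(idxs, key=lambda i: recording.channels[i].contact_index)
        if len(idxs) < 2:
            warnings.warn(
                f"shaft {shaft!r} has a single contact; no bipolar channel",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        for a, b in zip(idxs[:-1], idxs[1:]):
            ca, cb = recording.channels[a], recording.channels[b]
            rows.append(recording.data[a] - recording.data[b])
            infos.append(
                ChannelInfo(
                    label=f"{ca.label}-{cb.label}",
                    region=ca.region,
                    hemisphere=ca.hemisphere,
                    shaft_id=shaft,
                    contact_index=ca.contact_index,
                )
            )
    if not rows:
        raise ValueError("no shaft has two or more contacts")
    return recording.copy_with(data=np.vstack(rows), channels=infos)


def hfa_amplitude(recording: Recording, subbands=HFA_SUBBANDS) -> Recording:
    """Normalized analytic amplitude of the high-frequency (80-120 Hz) range.

    Each channel is band-passed into four 10-Hz-wide sub-bands, the
    magnitude of the analytic (Hilbert) signal is taken per sub-band, each
    sub-band trace is standardized by dividing by its own temporal mean, and
    the four normalized traces are averaged.  The output trace therefore has
    temporal mean ~1 on every channel.
    """
    fs = recording.sample_rate
    top = max(hi for _, hi in subbands)
    if fs < 2 * top:
        raise ValueError(
            f"sample rate {fs} Hz too low for {top} Hz sub-band (need >= {2 * top})"
        )
    acc = np.zeros_like(recording.data, dtype=float)
    for lo, hi in subbands:
        sos = _bandpass_sos(lo, hi, fs)
        bp = signal.sosfiltfilt(sos, recording.data, axis=-1)
        amp = np.abs(signal.hilbert(bp, axis=-1))
        mean = amp.mean(axis=-1, keepdims=True)
        # A flat (zero) sub-band would divide 0/0; map it to the neutral 1.
        safe = np.where(mean > 0, mean, 1.0)
        acc += np.where(mean > 0, amp / safe, 1.0)
    return recording.copy_with(data=acc / len(subbands))


def _robust_flag(stat: np.ndarray) -> np.ndarray:
    """True where ``stat > median + 2*IQR`` of ``stat``."""
    return stat > np.median(stat) + 2.0 * _iqr(stat)


def detect_artifact_channels(
    recording: Recording, hfa: Recording | None = None
) -> np.ndarray:
    """Retained-channel mask from the 2xIQR variance rule.

    A channel is flagged when its variance exceeds ``median + 2*IQR`` of the
    channel variances on either the broadband signal or the high-frequency
    amplitude trace (computed here if not supplied).  Returns a boolean mask
    that is True for retained channels.
    """
    if recording.n_channels < 4:
        raise ValueError("need >= 4 channels for a meaningful IQR rule")
    flags = _robust_flag(recording.data.var(axis=-1))
    if hfa is None:
        hfa = hfa_amplitude(recording)
    flags |= _robust_flag(hfa.data.var(axis=-1))
    return ~flags


def epoch(recording: Recording, epoch_length: float = 5.0) -> EpochSet:
    """Cut into non-overlapping ``epoch_length``-s epochs, dropping the
    trailing remainder (e.g. a 577-s run at 5 s yields 115 epochs)."""
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n_per = int(round(epoch_length * recording.sample_rate))
    n_ep = recording.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording of {recording.duration:.1f} s shorter than one "
            f"{epoch_length}-s epoch"
        )
    x = recording.data[:, : n_ep * n_per]
    data = x.reshape(recording.n_channels, n_ep, n_per).transpose(1, 0, 2)
    return EpochSet(
        data=data,
        sample_rate=recording.sample_rate,
        epoch_length=epoch_length,
        condition=recording.condition,
        channels=list(recording.channels),
        patient_id=recording.patient_id,
    )


def detect_artifact_epochs(epochs: EpochSet) -> np.ndarray:
    """Retained-epoch mask from the 2xIQR peak-amplitude rule.

    Per epoch the statistic is the maximum absolute amplitude over time,
    summed across *retained* channels only (apply the channel mask first);
    epochs whose statistic exceeds ``median + 2*IQR`` are flagged.  Returns
    the combined retained-epoch mask (existing rejections preserved).
    """
    if epochs.n_epochs < 4:
        raise ValueError("need >= 4 epochs for a meaningful IQR rule")
    x = epochs.data[:, epochs.channel_mask]
    stat = np.abs(x).max(axis=-1).sum(axis=-1)
    return epochs.epoch_mask & ~_robust_flag(stat)


def notch_line_noise(
    recording: Recording, base: float = 50.0, max_harmonic_hz: float = 200.0, q: float = 30.0
) -> Recording:
    """Notch out power-line interference at ``base`` Hz and harmonics.

    Intended for real recordings; the synthetic generator injects no line
    noise, so the pipeline leaves this off by default.
    """
    fs = recording.sample_rate
    data = recording.data
    f = base
    while f <= min(max_harmonic_hz, fs / 2 - 1):
        b, a = signal.iirnotch(f, q, fs=fs)
        data = signal.filtfilt(b, a, data, axis=-1)
        f += base
    return recording.copy_with(data=data)
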