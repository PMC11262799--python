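"""Core containers for multichannel intracranial recordings.

A :class:`Recording` is one patient x condition run: a real-valued
``channels x samples`` matrix (microvolts) plus per-channel metadata
(anatomical region as an opaque string, hemisphere, electrode shaft and
contact index).  An :class:`EpochSet` is the same data cut into
non-overlapping fixed-length epochs — the exchangeable unit for every
resampling procedure downstream (permutation tests, surrogate nulls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("speech", "music", "baseline_tones", "baseline_syllables")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one (virtual) channel."""

    label: str
    region: str = "unknown"
    hemisphere: str = "L"
    shaft_id: str = "A"
    contact_index: int = 0


@dataclass
class Recording:
    """One patient x condition multichannel time series.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    condition : str
        One of ``speech``, ``music``, ``baseline_tones``,
        ``baseline_syllables``.
    sample_rate : float
        Sampling rate in Hz.  Must exceed twice the highest analysis
        frequency (250 Hz for the 80-120 Hz high-frequency band).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channels : list of ChannelInfo
    """

    patient_id: str
    condition: str
    sample_rate: float
    data: np.ndarray
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel records for "
                f"{self.data.shape[0]} data rows"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Run duration in seconds."""
        return self.n_samples / self.sample_rate

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs of a recording.

    ``data`` has shape ``(n_epochs, n_channels, n_samples_per_epoch)``.
    ``channel_mask`` and ``epoch_mask`` are True for *retained*
    channels/epochs; artifact rejection only ever clears bits, never sets
    them.
    """

    data: np.ndarray
    sample_rate: float
    epoch_length: float
    condition: str
    channels: list[ChannelInfo]
    patient_id: str = ""
    channel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        n_ep, n_ch, n_s = self.data.shape
        expected = int(round(self.epoch_length * self.sample_rate))
        if n_s != expected:
            raise ValueError(
                f"epoch has {n_s} samples, expected {expected} "
                f"({self.epoch_length} s at {self.sample_rate} Hz)"
            )
        if self.channel_mask is None:
            self.channel_mask = np.ones(n_ch, dtype=bool)
        if self.epoch_mask is None:
            self.epoch_mask = np.ones(n_ep, dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        self.epoch_mask = np.asarray(self.epoch_mask, dtype=bool)
        if self.channel_mask.shape != (n_ch,) or self.epoch_mask.shape != (n_ep,):
            raise ValueError("mask lengths must match data dimensions")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def retained(self) -> np.ndarray:
        """Data restricted to retained epochs and channels."""
        return self.data[self.epoch_mask][:, self.channel_mask]


def read_edf(path, patient_id: str, condition: str,
             region_map: dict | None = None) -> Recording:
    """Load a real EDF recording (requires mne).

    Channel labels of the form ``<shaft><index>`` (e.g. ``A1``, ``TP12``)
    are parsed into shaft/contact metadata; ``region_map`` optionally maps
    labels to anatomical region strings.
    """
    import re

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = []
    for label in raw.ch_names:
        m = re.match(r"([A-Za-z']+)(\d+)$", label.strip())
        shaft = m.group(1) if m else label
        contact = int(m.group(2)) if m else 0
        channels.append(
            ChannelInfo(
                label=label,
                region=(region_map or {}).get(label, "unknown"),
                hemisphere="R" if shaft.endswith("'") else "L",
                shaft_id=shaft,
                contact_index=contact,
            )
        )
    return Recording(
        patient_id=patient_id,
        condition=condition,
        sample_rate=float(raw.info["sfreq"]),
        data=data,
        channels=channels,
    )
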