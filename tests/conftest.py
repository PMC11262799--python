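import numpy as np
import pytest

from neuroshare.recording import ChannelInfo, EpochSet, Recording


def make_recording(
    data: np.ndarray,
    sample_rate: float = 500.0,
    condition: str = "speech",
    patient_id: str = "P00",
    shaft_size: int | None = None,
) -> Recording:
    """Wrap a channels x samples array, one shaft per channel by default."""
    n_ch = data.shape[0]
    chans = []
    for i in range(n_ch):
        if shaft_size:
            shaft, contact = f"S{i // shaft_size}", i % shaft_size
        else:
            shaft, contact = f"S{i}", 0
        chans.append(
            ChannelInfo(
                label=f"ch{i}", region=f"region_{i % 3}", shaft_id=shaft,
                contact_index=contact,
            )
        )
    return Recording(
        patient_id=patient_id,
        condition=condition,
        sample_rate=sample_rate,
        data=data,
        channels=chans,
    )


def make_epochs(
    data: np.ndarray,
    sample_rate: float = 500.0,
    epoch_length: float = 5.0,
    condition: str = "speech",
    shaft_size: int | None = None,
) -> EpochSet:
    n_ch = data.shape[1]
    chans = []
    for i in range(n_ch):
        if shaft_size:
            shaft, contact = f"S{i // shaft_size}", i % shaft_size
        else:
            shaft, contact = f"S{i}", 0
        chans.append(ChannelInfo(label=f"ch{i}", shaft_id=shaft, contact_index=contact))
    return EpochSet(
        data=data,
        sample_rate=sample_rate,
        epoch_length=epoch_length,
        condition=condition,
        channels=chans,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
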