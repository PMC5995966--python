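"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the standard 10-20 montage (classic naming,
#: i.e. T3/T4/T5/T6 rather than T7/T8/P7/P8), in montage order.
CHANNELS_1020: tuple[str, ...] = (
    "C3", "Cz", "C4", "F7", "F3", "Fz", "F4", "F8", "P3", "Pz", "P4",
    "T3", "T4", "T5", "T6", "Fp1", "Fp2", "O1", "O2",
)


def normalize_channel(name: str) -> str:
    """Map a channel label to its canonical capitalization (case-insensitive)."""
    lookup = {c.upper(): c for c in CHANNELS_1020}
    try:
        return lookup[name.upper()]
    except KeyError:
        raise KeyError(f"unknown 10-20 channel label: {name!r}") from None


@dataclass
class EpochedRecording:
    """Stimulus-locked multichannel epochs.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples, n_epochs)`` in signal units
        (microvolts for EEG).
    fs
        Sampling rate in Hz.
    channels
        Channel labels, one per row of ``data``.
    labels
        Per-epoch class label (e.g. ``"familiar"`` / ``"unfamiliar"``).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, epochs)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list does not match data rows")
        if self.labels and len(self.labels) != self.data.shape[2]:
            raise ValueError("labels do not match number of epochs")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    def epoch(self, i: int) -> np.ndarray:
        """Return epoch ``i`` as a (channels, samples) view."""
        return self.data[:, :, i]


def window_n_samples(window_ms: tuple[float, float], fs: float) -> int:
    """Sample count of a half-open window [t0, t1) in ms at rate ``fs``."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    return int(round((t1 - t0) * fs / 1000.0))
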