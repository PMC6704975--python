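"""Core container for multichannel EEG data.

An :class:`EEGRecording` is a channels x samples matrix of scalp potentials
(in microvolts) together with its sampling rate and channel labels.  Every
stage of the microstate pipeline consumes and produces this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Multichannel EEG recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, scalp potential in uV.
    fs
        Sampling rate in Hz.
    channel_labels
        One identifier per channel.  Auto-generated (``E001`` ...) if omitted.
    subject, group
        Optional subject identifier and group tag (``"patient"`` or
        ``"control"``) carried through to the statistics stage.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError(f"need at least 2 channels, got {self.data.shape[0]}")
        if self.data.shape[1] < 2:
            raise ValueError(f"need at least 2 samples, got {self.data.shape[1]}")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"E{i + 1:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new data (and optionally new fs)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)
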