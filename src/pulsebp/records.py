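"""Core waveform container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WaveformRecording:
    """A multi-channel sampled pulse-wave signal.

    Parameters
    ----------
    channels : np.ndarray, shape (n_channels, n_samples)
        Sampled signals in arbitrary amplitude units. All channels share
        the same time base.
    sampling_rate_hz : float
        Sampling rate, strictly positive.
    record_id, subject_id : str
        Identity of the recording and of the participant it came from.
    """

    channels: np.ndarray
    sampling_rate_hz: float
    record_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.ndim != 2 or self.channels.shape[0] < 1:
            raise ValueError("channels must be a (n_channels, n_samples) array")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channels contain non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        """Time axis: sample index divided by the sampling rate (0-based)."""
        return np.arange(self.n_samples) / self.sampling_rate_hz
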