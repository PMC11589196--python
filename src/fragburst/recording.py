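"""The multichannel extracellular recording container.

A :class:`Recording` is the common currency of the package: simulated
virtual-electrode output, synthetic fixtures and experimental exports all
flow through it into the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """Voltage matrix (channels x samples, µV) with sampling rate (Hz)."""

    voltage: np.ndarray
    fs: float
    channel_ids: list = field(default_factory=list)
    well_id: str = "well0"

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be 2-D (channels x samples)")
        if not self.channel_ids:
            self.channel_ids = [f"el{i}" for i in range(self.voltage.shape[0])]
        if len(self.channel_ids) != self.voltage.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs

    def slice_time(self, t0: float, t1: float) -> "Recording":
        """Sub-recording covering [t0, t1) seconds."""
        i0 = max(0, int(round(t0 * self.fs)))
        i1 = min(self.n_samples, int(round(t1 * self.fs)))
        return Recording(
            voltage=self.voltage[:, i0:i1],
            fs=self.fs,
            channel_ids=list(self.channel_ids),
            well_id=self.well_id,
        )
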