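"""In-memory containers for multichannel sEMG recordings and envelopes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .grid import GridLayout

__all__ = ["EmgRecording", "EnvelopeMatrix"]


@dataclass
class EmgRecording:
    """Monopolar multichannel surface-EMG recording.

    ``data`` is channels x samples; channel ordering follows
    :meth:`GridLayout.channel_index`.  ``bad_mask`` marks channels with bad
    electrode-skin contact; masked channels are excluded from all downstream
    maps and statistics.
    """

    data: np.ndarray
    fs: float
    grid: GridLayout
    bad_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"expected {self.grid.n_channels} channels, got {self.data.shape[0]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
            if self.bad_mask.shape != (self.data.shape[0],):
                raise ValueError("bad_mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EmgRecording":
        return replace(self, data=data)


@dataclass
class EnvelopeMatrix:
    """Rectified-and-smoothed sEMG amplitude, channels x samples, nonnegative."""

    env: np.ndarray
    fs: float
    grid: GridLayout
    bad_mask: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        if self.env.ndim != 2:
            raise ValueError("env must be channels x samples")
        if (self.env < 0).any():
            raise ValueError("envelope must be nonnegative")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.env.shape[0], dtype=bool)
        else:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.env.shape[0]
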