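"""Core in-memory containers shared across the pipeline.

The continuous unit is an :class:`EEGRecording` (channels x samples); the
epoched unit is an :class:`EpochArray` (epochs x channels x samples).  Both are
thin dataclasses around NumPy arrays: heavier containers (``mne.io.Raw``) are
constructed on demand inside the preprocessing routines that need sensor
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording", "EpochArray", "DyadEpochPair", "InvalidConfigError"]


class InvalidConfigError(ValueError):
    """A configuration object violates one of its invariants."""


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, arbitrary units (we keep
        whatever units the generator or file provided; filters are linear).
    sfreq
        Sampling frequency in Hz.
    ch_names
        One unique name per channel.
    bads
        Names of channels flagged for interpolation.
    positions
        Optional ``(n_channels, 3)`` unit-sphere sensor positions (meters,
        head-centered), required by spherical-spline interpolation.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    bads: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (C, N), got shape {self.data.shape}")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if not set(self.bads) <= set(self.ch_names):
            raise ValueError("bads must be a subset of ch_names")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be (C, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self, data: np.ndarray | None = None) -> "EEGRecording":
        """Shallow-config, deep-data copy (optionally with replaced samples)."""
        return replace(
            self,
            data=np.array(self.data if data is None else data),
            ch_names=list(self.ch_names),
            bads=list(self.bads),
            positions=None if self.positions is None else np.array(self.positions),
        )


@dataclass
class EpochArray:
    """Fixed-length epochs cut from one recording.

    ``data`` is ``(E, C, T)`` with ``T = round(epoch_len * sfreq) + 1``: epochs
    use an inclusive-endpoint convention so a 1-s epoch at 500 Hz has 501
    samples, and consecutive epochs share exactly one boundary sample.
    ``kept_indices`` maps rows back to the original epoch grid (identity until
    artifact rejection drops rows).
    """

    data: np.ndarray
    sfreq: float
    epoch_len: float
    kept_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (E, C, T), got {self.data.shape}")
        expected_t = round(self.epoch_len * self.sfreq) + 1
        if self.data.shape[0] > 0 and self.data.shape[2] != expected_t:
            raise ValueError(
                f"T={self.data.shape[2]} inconsistent with epoch_len={self.epoch_len}"
                f" at sfreq={self.sfreq} (expected {expected_t})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.kept_indices is None:
            self.kept_indices = np.arange(self.data.shape[0])
        else:
            self.kept_indices = np.asarray(self.kept_indices, dtype=int)
            if self.kept_indices.shape != (self.data.shape[0],):
                raise ValueError("kept_indices must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass
class DyadEpochPair:
    """Two time-aligned single-participant epochs from one dyad.

    ``label`` is 1 for a mixed (ASC-TD) dyad and 0 for a control (TD-TD) dyad.
    """

    x1: np.ndarray
    x2: np.ndarray
    dyad_id: str
    label: int

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape:
            raise ValueError("x1 and x2 must have identical shapes")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
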