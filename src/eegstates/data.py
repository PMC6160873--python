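"""Core data container for multi-trial, multi-channel time series.

The pipeline operates on a channels x samples x trials tensor with a
per-trial condition label, the standard layout for epoched task EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input has zero variance where variance is required."""


@dataclass
class TrialTensor:
    """Epoched multi-channel data.

    Parameters
    ----------
    data : ndarray, shape (m, n, d)
        Channels x samples x trials.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per channel.
    condition : ndarray of str, shape (d,)
        Per-trial condition label.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    condition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (channels, samples, trials), got {self.data.shape}")
        m, n, d = self.data.shape
        if m < 2:
            raise ValueError(f"need at least 2 channels, got {m}")
        if d < 2:
            raise ValueError(f"need at least 2 trials, got {d}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(m)]
        if len(self.channel_names) != m:
            raise ValueError("channel_names length must match channel count")
        if self.condition is None:
            self.condition = np.array(["cond0"] * d)
        self.condition = np.asarray(self.condition)
        if self.condition.shape != (d,):
            raise ValueError("condition must have one label per trial")
        for c in self.conditions():
            if int(np.sum(self.condition == c)) < 2:
                raise ValueError(f"condition {c!r} has fewer than 2 trials")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def conditions(self) -> list:
        """Condition labels in order of first appearance."""
        seen: list = []
        for c in self.condition:
            if c not in seen:
                seen.append(c)
        return seen

    def select_condition(self, label) -> np.ndarray:
        """Return the (m, n, d_c) sub-array for one condition."""
        mask = self.condition == label
        if not mask.any():
            raise KeyError(f"no trials with condition {label!r}")
        return self.data[:, :, mask]

    def copy_with(self, data: np.ndarray, condition: np.ndarray | None = None) -> "TrialTensor":
        return TrialTensor(
            data=np.array(data, dtype=float),
            fs=self.fs,
            channel_names=list(self.channel_names),
            condition=np.array(self.condition if condition is None else condition),
        )
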