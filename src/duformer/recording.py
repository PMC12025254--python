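"""Core data containers: continuous recordings and epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .montage import CHANNELS


@dataclass
class RawRecording:
    """A continuous multi-channel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channel_names : tuple of str
        Ordered electrode labels; rows of ``data`` follow this order.
    sample_rate : float
        Sampling rate in Hz.
    subject_id : str
        Subject identifier.
    session : str
        Session / class tag (e.g. ``"pre"`` / ``"post"`` or ``"T1"`` / ``"T5"``).
    extras : dict
        Optional side information (e.g. the clean signal and ground-truth
        artifact trace attached by the synthetic generator).
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    sample_rate: float = 1000.0
    subject_id: str = ""
    session: str = ""
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, data: np.ndarray, **extras: Any) -> "RawRecording":
        """A copy carrying new data and (optionally) additional extras."""
        new = replace(self, data=np.asarray(data, dtype=float))
        new.extras = {**self.extras, **extras}
        return new


@dataclass
class SegmentSet:
    """Fixed-length epochs cut from one or more recordings of one band.

    ``segments`` is (n, n_channels, window_samples); ``labels`` holds the
    binary class of each epoch (0 = pre, 1 = post) and ``subject_ids`` the
    originating subject, enabling subject-wise cross-validation splits.
    """

    band: str
    segments: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.segments.ndim != 3:
            raise ValueError("segments must be 3-D (n, channels, samples)")
        n = self.segments.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == n):
            raise ValueError("segments, labels and subject_ids disagree in length")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return self.segments.shape[0]

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            self.band, self.segments[idx], self.labels[idx], self.subject_ids[idx]
        )

    @classmethod
    def concatenate(cls, parts: list["SegmentSet"]) -> "SegmentSet":
        """Stack several sets of the same band into one."""
        if not parts:
            raise ValueError("nothing to concatenate")
        bands = {p.band for p in parts}
        if len(bands) > 1:
            raise ValueError(f"mixed bands: {sorted(bands)}")
        return cls(
            parts[0].band,
            np.concatenate([p.segments for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
        )
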