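"""Core data model: stimulus sequences and raw multichannel EEG recordings.

A recording is a plain in-memory container — channels x samples in microvolts
at a fixed sampling rate, plus the stimulus markers that downstream epoching
locks onto. Scalp channels are the three midline sites Fz, Cz, Pz; a fourth
EOG channel carries the ocular reference used for artifact correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCALP_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz")
EOG_CHANNEL = "EOG"
DEFAULT_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + (EOG_CHANNEL,)

#: Event kinds emitted by the stimulus generators.
EVENT_KINDS = ("standard_tone", "deviant_tone", "word_prime", "word_target")
EVENT_CONDITIONS = ("standard", "deviant", "congruent", "incongruent", "none")


@dataclass
class StimulusSequence:
    """Ordered stimulus events: onset times (s), kinds and conditions."""

    onsets: np.ndarray  # seconds, strictly increasing
    kinds: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) != len(self.kinds) or len(self.onsets) != len(self.conditions):
            raise ValueError("onsets, kinds and conditions must have equal length")
        if len(self.onsets):
            if np.any(self.onsets < 0):
                raise ValueError("stimulus onsets must be >= 0")
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("stimulus onsets must be strictly increasing")
        for k in self.kinds:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")
        for c in self.conditions:
            if c not in EVENT_CONDITIONS:
                raise ValueError(f"unknown event condition {c!r}")

    def __len__(self) -> int:
        return len(self.onsets)

    def select(self, *, kind: str | None = None, condition: str | None = None) -> "StimulusSequence":
        """Subsequence matching the given kind and/or condition."""
        keep = np.ones(len(self), dtype=bool)
        if kind is not None:
            keep &= np.array([k == kind for k in self.kinds])
        if condition is not None:
            keep &= np.array([c == condition for c in self.conditions])
        idx = np.flatnonzero(keep)
        return StimulusSequence(
            onsets=self.onsets[idx],
            kinds=[self.kinds[i] for i in idx],
            conditions=[self.conditions[i] for i in idx],
        )

    def shifted(self, offset: float) -> "StimulusSequence":
        """Same events with all onsets moved by ``offset`` seconds."""
        return StimulusSequence(self.onsets + offset, list(self.kinds), list(self.conditions))

    @staticmethod
    def concatenate(*seqs: "StimulusSequence") -> "StimulusSequence":
        """Merge sequences, sorting events by onset."""
        onsets = np.concatenate([s.onsets for s in seqs]) if seqs else np.empty(0)
        kinds = [k for s in seqs for k in s.kinds]
        conditions = [c for s in seqs for c in s.conditions]
        order = np.argsort(onsets, kind="stable")
        return StimulusSequence(onsets[order], [kinds[i] for i in order], [conditions[i] for i in order])


@dataclass
class RawRecording:
    """Multichannel sampled EEG in microvolts with aligned stimulus markers."""

    sample_rate: float
    channels: list[str]
    data: np.ndarray  # (n_channels, n_samples), uV
    markers: StimulusSequence = field(default_factory=lambda: StimulusSequence(np.empty(0), [], []))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching `channels`")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """1-D view of one channel's samples (uV)."""
        try:
            i = self.channels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording") from err
        return self.data[i]

    def scalp_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c != EOG_CHANNEL]

    def with_data(self, data: np.ndarray) -> "RawRecording":
        """Copy of this recording carrying new sample data."""
        return RawRecording(self.sample_rate, list(self.channels), data, self.markers)

    def marker_samples(self) -> np.ndarray:
        """Marker onsets converted to integer sample indices (nearest sample)."""
        return np.rint(self.markers.onsets * self.sample_rate).astype(int)
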