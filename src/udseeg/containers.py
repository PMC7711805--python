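"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import CHANNELS_10_20, NUDS, UDS

__all__ = ["ContinuousRecording", "EpochSet", "FeatureMatrix", "RejectionReport"]

_VALID_LABELS = frozenset({UDS, NUDS})


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG with event markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-20 montage names, one per row of ``data``.
    markers : list of (int, str)
        Event markers as (sample_index, class_label) with labels in
        {"UDS", "NUDS"}.
    artifacts : list of (int, int)
        Injected-artifact positions as (channel_index, sample_index);
        filled by the synthetic generator so tests can assert on the
        rejection stage, empty for real recordings.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[tuple[int, str]]
    artifacts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one channel label per data row required")
        n = self.data.shape[1]
        for idx, lab in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker index {idx} outside [0, {n})")
            if lab not in _VALID_LABELS:
                raise ValueError(f"marker label {lab!r} not in {{UDS, NUDS}}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length, event-locked epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples); the time axis
    covers [-pre_ms, post_ms) around the marker, so sample ``pre_ms*fs/1000``
    is the marker onset.
    """

    data: np.ndarray
    labels: np.ndarray          # class per epoch, {"UDS","NUDS"}
    participant_ids: np.ndarray
    fs: float
    channel_labels: list[str]
    window: tuple[float, float] = (100.0, 900.0)  # (pre_ms, post_ms)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.participant_ids = np.asarray(self.participant_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        if len(self.participant_ids) != self.data.shape[0]:
            raise ValueError("one participant id per epoch required")
        pre_ms, post_ms = self.window
        expect = int(round((pre_ms + post_ms) * self.fs / 1000.0))
        if self.data.shape[0] and self.data.shape[2] != expect:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != window length {expect}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_baseline_samples(self) -> int:
        """Samples in the pre-marker interval [-pre_ms, 0)."""
        return int(round(self.window[0] * self.fs / 1000.0))

    def select(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.data[idx],
            self.labels[idx],
            self.participant_ids[idx],
            self.fs,
            list(self.channel_labels),
            self.window,
        )


@dataclass
class RejectionReport:
    """Outcome of amplitude-based artifact screening."""

    n_input: int
    rejected_indices: np.ndarray
    retention_warning_at: float = 0.80

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_indices)

    @property
    def retention_fraction(self) -> float:
        if self.n_input == 0:
            return 1.0
        return (self.n_input - self.n_rejected) / self.n_input

    @property
    def low_retention_warning(self) -> bool:
        return self.retention_fraction < self.retention_warning_at


@dataclass
class FeatureMatrix:
    """Per-epoch, per-channel scalar features with class labels.

    ``values`` is (n_epochs, n_channels) with columns in the fixed montage
    order; rows where the estimator was undefined carry NaN until filtered
    by the extraction step.
    """

    values: np.ndarray
    labels: np.ndarray
    channel_labels: list[str]
    participant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.participant_ids = np.asarray(self.participant_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs x channels)")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.channel_labels):
            raise ValueError("one channel label per column required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def rows_for(self, label: str) -> np.ndarray:
        return self.values[self.labels == label]

    def select(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            list(self.channel_labels),
            self.participant_ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: ``participant``, ``label``, then one channel column each."""
        df = pd.DataFrame(self.values, columns=list(self.channel_labels))
        df.insert(0, "label", self.labels)
        df.insert(0, "participant", self.participant_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = [c for c in ("participant", "label") if c in df.columns]
        channels = [c for c in df.columns if c not in meta]
        return cls(
            df[channels].to_numpy(dtype=float),
            df["label"].to_numpy() if "label" in meta else np.array([], dtype=object),
            channels,
            df["participant"].to_numpy()
            if "participant" in meta
            else np.zeros(len(df), dtype=int),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


def default_channel_labels() -> list[str]:
    return list(CHANNELS_10_20)
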