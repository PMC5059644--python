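"""Observation features for recognition.

The recognizer consumes the raw channel values frame-by-frame at the
sampling rate; no windowing or delta features are applied.  Two feature
views exist:

* the six-dimensional vector of the measurement channels CH1..CH6, and
* a two-dimensional projection used by the threshold baseline and for
  channel-count comparisons: horizontal = CH2 - CH5 (left minus right
  temple) and vertical = mean(CH1, CH6) - mean(CH3, CH4) (above minus
  below the eyes).

Per-recording mean removal is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic_eog import EOGRecording

__all__ = [
    "FeatureSequence",
    "six_channel_features",
    "two_channel_features",
    "features_to_csv",
    "features_from_csv",
]


@dataclass
class FeatureSequence:
    """Time-ordered observation vectors at the recording frame rate."""

    vectors: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a (time, dim) matrix")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vectors)


def _check_channels(rec: EOGRecording) -> None:
    if rec.n_channels != 6:
        raise ValueError(f"expected 6 channels, got {rec.n_channels}")


def six_channel_features(rec: EOGRecording, mean_removal: bool = False) -> FeatureSequence:
    """Identity per-sample mapping of the six channels."""
    _check_channels(rec)
    x = rec.samples.copy()
    if mean_removal:
        x -= x.mean(axis=0, keepdims=True)
    return FeatureSequence(x, rec.sample_rate)


def two_channel_features(rec: EOGRecording, mean_removal: bool = False) -> FeatureSequence:
    """Horizontal/vertical difference projection of the six channels."""
    _check_channels(rec)
    s = rec.samples
    horizontal = s[:, 1] - s[:, 4]
    vertical = (s[:, 0] + s[:, 5]) / 2.0 - (s[:, 2] + s[:, 3]) / 2.0
    x = np.column_stack([horizontal, vertical])
    if mean_removal:
        x -= x.mean(axis=0, keepdims=True)
    return FeatureSequence(x, rec.sample_rate)


def features_to_csv(fs: FeatureSequence, path: str | Path) -> None:
    header = ",".join(f"f{i}" for i in range(fs.dim))
    np.savetxt(Path(path), fs.vectors, delimiter=",", header=header,
               comments="", fmt="%.8g")


def features_from_csv(path: str | Path, frame_rate: float = 100.0) -> FeatureSequence:
    return FeatureSequence(np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2),
                           frame_rate)
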