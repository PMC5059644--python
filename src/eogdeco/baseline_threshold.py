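"""Threshold-based eye-motion recognition (the conventional baseline).

Each sample of the two-dimensional EOG vector (horizontal, vertical) is
classified independently: if its norm is below a threshold the sample
is "center"; otherwise the direction whose unit vector -- (1,0) left,
(0,1) up, (-1,0) right, (0,-1) down -- has the largest inner product
with the sample wins (ties broken in that fixed order).  Because the
per-sample decisions are noisy, a sliding majority vote (1000 ms
window, 10 ms shift by default) smooths the label stream, and
consecutive identical labels are merged into single motion events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSequence
from .synthetic_eog import MOTIONS

__all__ = ["ThresholdConfig", "classify_samples", "vote_filter", "merge_events",
           "baseline_recognize"]

# classification order fixes tie-breaking: left, up, right, down
_DIRECTIONS = ("left", "up", "right", "down")
_UNIT_VECTORS = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])


@dataclass(frozen=True)
class ThresholdConfig:
    """Baseline parameters; the threshold is in the feature's uV scale."""

    center_threshold: float = 300.0
    vote_window_ms: float = 1000.0
    vote_shift_ms: float = 10.0
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.center_threshold <= 0:
            raise ValueError("center_threshold must be positive")
        if not (self.vote_window_ms >= self.vote_shift_ms > 0):
            raise ValueError("need vote_window_ms >= vote_shift_ms > 0")


def classify_samples(features: FeatureSequence | np.ndarray,
                     config: ThresholdConfig) -> list[str]:
    """Per-sample motion decision on the 2-D feature at the sampling rate."""
    x = features.vectors if isinstance(features, FeatureSequence) else np.asarray(features)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("baseline classification requires 2-D features")
    products = x @ _UNIT_VECTORS.T  # (T, 4)
    best = np.argmax(products, axis=1)  # first max wins: left > up > right > down
    labels = [_DIRECTIONS[b] for b in best]
    center = np.linalg.norm(x, axis=1) < config.center_threshold
    return ["center" if c else lab for c, lab in zip(center, labels)]


def vote_filter(labels: list[str], config: ThresholdConfig) -> list[str]:
    """Sliding-window majority vote over the per-sample labels.

    One label is emitted per window shift; a signal shorter than one
    window yields a single vote over the available samples.  Vote ties
    go to the motion earliest in the canonical order.
    """
    if not labels:
        return []
    fs = config.sample_rate
    win = max(1, round(config.vote_window_ms / 1000.0 * fs))
    shift = max(1, round(config.vote_shift_ms / 1000.0 * fs))
    codes = np.array([MOTIONS.index(lab) for lab in labels])
    T = len(codes)
    if T <= win:
        counts = np.bincount(codes, minlength=len(MOTIONS))
        return [MOTIONS[int(np.argmax(counts))]]
    out = []
    for start in range(0, T - win + 1, shift):
        counts = np.bincount(codes[start : start + win], minlength=len(MOTIONS))
        out.append(MOTIONS[int(np.argmax(counts))])
    return out


def merge_events(labels: list[str]) -> list[str]:
    """Run-length collapse of consecutive identical labels."""
    out: list[str] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def baseline_recognize(features: FeatureSequence, config: ThresholdConfig) -> list[str]:
    """Full baseline pipeline: classify, vote, merge."""
    return merge_events(vote_filter(classify_samples(features, config), config))
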