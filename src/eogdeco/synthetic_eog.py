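"""Synthetic multi-channel electrooculography (EOG) recordings.

EOG observes the corneoretinal potential through skin electrodes placed
around the eyes; the measured voltage tracks gaze direction with a
magnitude of roughly 290-1100 uV per radian of deflection and spectral
content essentially confined below 30 Hz.  This module emulates the
six-electrode montage used for continuous eye-motion input: two channels
above the eyes (CH1, CH6), two below (CH3, CH4) and one at each temple
(CH2 left, CH5 right).

A recording is produced from a latent two-dimensional gaze trajectory.
Each motion in a sequence drives a saccade-like logistic transition of
the gaze state from wherever it currently is to the motion's target
position, followed by a hold period.  Because the transition starts from
the *previous* gaze position, the rendered waveform of a motion depends
on its context: "center" after "up" descends, while "center" after
"down" ascends.  The latent trajectory is projected to the six channels
by a fixed channel-geometry matrix, and slow electrode drift plus
band-limited measurement noise are added.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import signal as _sig

__all__ = [
    "MOTIONS",
    "SIL",
    "GAZE_TARGETS",
    "CHANNEL_GEOMETRY",
    "MotionSequence",
    "UserProfile",
    "EOGRecording",
    "generate_recording",
    "generate_corpus",
    "random_motion_sequence",
    "write_recording",
    "read_recording",
]

#: The five eye motions used for character input.
MOTIONS = ("up", "down", "left", "right", "center")

#: Label for boundary periods in which no motion is performed (gaze at center).
SIL = "sil"

#: Latent gaze targets on the unit circle (horizontal x, vertical y).
GAZE_TARGETS = {
    "up": (0.0, 1.0),
    "down": (0.0, -1.0),
    "left": (1.0, 0.0),
    "right": (-1.0, 0.0),
    "center": (0.0, 0.0),
    SIL: (0.0, 0.0),
}

# Rows CH1..CH6, columns (horizontal, vertical), unit amplitude.  CH1/CH6
# sit above the eyes (positive for "up"), CH3/CH4 below (positive for
# "down"), CH2 at the left temple (positive for "left") and CH5 at the
# right temple (positive for "right").  The small off-axis terms model
# imperfect electrode placement and make the six channels carry slightly
# more information than the two derived difference channels.
CHANNEL_GEOMETRY = np.array(
    [
        [0.05, 0.55],  # CH1
        [0.55, 0.03],  # CH2
        [0.02, -0.42],  # CH3
        [0.18, -0.55],  # CH4
        [-0.45, 0.10],  # CH5
        [0.20, 0.38],  # CH6
    ]
)

# per-entry scale of the user-specific electrode-placement perturbation
_GEOMETRY_SCALE = 0.5

_NOISE_CUTOFF_HZ = 27.0
_NOISE_NTAPS = 101


@dataclass(frozen=True)
class MotionSequence:
    """An ordered sequence of eye motions.

    Adjacent motions must differ: a repeated motion (eyes staying put)
    has no detectable boundary, so the input protocol forbids it.
    """

    motions: tuple[str, ...]

    def __init__(self, motions: Iterable[str]):
        object.__setattr__(self, "motions", tuple(motions))
        for m in self.motions:
            if m not in MOTIONS:
                raise ValueError(f"unknown motion {m!r}")
        for a, b in zip(self.motions, self.motions[1:]):
            if a == b:
                raise ValueError(f"adjacent repeated motion {a!r}")

    def __len__(self) -> int:
        return len(self.motions)

    def __iter__(self):
        return iter(self.motions)

    def __getitem__(self, i):
        return self.motions[i]


@dataclass(frozen=True)
class UserProfile:
    """Per-user signal parameters of the generator.

    Parameters
    ----------
    amplitude_scale
        Projection gain in uV per unit gaze deflection; the physiological
        range is roughly 290-1100 uV/rad.
    motion_duration_mean, motion_duration_std
        Seconds each motion occupies (transition + hold); jittered per
        motion.
    noise_std
        Standard deviation in uV of the broadband measurement noise
        before band-limiting to <30 Hz.
    drift_rate
        Electrode drift modelled as an integrated Gaussian random walk;
        its standard deviation grows as ``drift_rate * sqrt(t seconds)``.
    rise_time
        Saccade transition time constant (logistic ramp), seconds.  A
        rise time comparable to or longer than the motion duration
        produces the undershoot typical of fast continuous input: the
        gaze never settles on the target, so the rendered shape and
        endpoint of a motion depend strongly on the preceding context.
    gain_jitter_std
        Multiplicative per-motion variability of the gaze deflection
        (natural trial-to-trial saccade gain variation).
    geometry_jitter, geometry_seed
        User-specific perturbation of the channel-geometry matrix,
        emulating individual electrode placement and skin-contact
        differences; fixed per user (seeded by ``geometry_seed``),
        with per-entry standard deviation ``geometry_jitter`` times
        half the nominal main coefficient.
    sil_duration
        Motionless padding at the recording boundaries, seconds.
    """

    amplitude_scale: float = 600.0
    motion_duration_mean: float = 0.4
    motion_duration_std: float = 0.1
    noise_std: float = 15.0
    drift_rate: float = 10.0
    rise_time: float = 0.10
    gain_jitter_std: float = 0.1
    geometry_jitter: float = 0.0
    geometry_seed: int = 0
    sil_duration: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self):
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if not (290.0 <= self.amplitude_scale <= 1100.0):
            warnings.warn(
                "amplitude_scale outside the physiological 290-1100 uV range",
                stacklevel=2,
            )
        if self.motion_duration_mean <= 0:
            raise ValueError("motion_duration_mean must be positive")
        if self.motion_duration_std < 0 or self.noise_std < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.rise_time <= 0:
            raise ValueError("rise_time must be positive")
        if self.gain_jitter_std < 0:
            raise ValueError("gain_jitter_std must be non-negative")
        if self.geometry_jitter < 0:
            raise ValueError("geometry_jitter must be non-negative")
        if self.sil_duration < 0:
            raise ValueError("sil_duration must be non-negative")


@dataclass
class EOGRecording:
    """A sampled six-channel EOG signal with an optional label track.

    ``labels`` is a list of ``(start_sample, end_sample, label)`` with
    half-open, non-overlapping, sorted segments covering ``[0, len)``
    when produced by the generator.  Labels are motion names or "sil".
    """

    samples: np.ndarray
    sample_rate: float = 100.0
    labels: Optional[list[tuple[int, int, str]]] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (time, channels) matrix")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.labels is not None:
            prev_end = 0
            for start, end, lab in self.labels:
                if not (0 <= start < end <= len(self.samples)):
                    raise ValueError(f"label segment ({start}, {end}) out of range")
                if start < prev_end:
                    raise ValueError("label segments overlap or are unsorted")
                prev_end = end

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def __len__(self) -> int:
        return len(self.samples)

    def motion_sequence(self) -> MotionSequence:
        """Labelled motions (silence segments dropped)."""
        if self.labels is None:
            raise ValueError("recording has no label track")
        return MotionSequence(lab for _, _, lab in self.labels if lab != SIL)


def _noise_taps(sample_rate: float) -> np.ndarray:
    nyq = sample_rate / 2.0
    cutoff = min(_NOISE_CUTOFF_HZ, 0.9 * nyq)
    return _sig.firwin(_NOISE_NTAPS, cutoff, fs=sample_rate)


def _band_limited_noise(rng, n, n_ch, std, sample_rate):
    """White Gaussian noise low-pass filtered to <30 Hz (zero phase FIR)."""
    if std == 0:
        return np.zeros((n, n_ch))
    white = rng.normal(0.0, std, size=(n + 4 * _NOISE_NTAPS, n_ch))
    taps = _noise_taps(sample_rate)
    out = _sig.filtfilt(taps, [1.0], white, axis=0)
    return out[2 * _NOISE_NTAPS : 2 * _NOISE_NTAPS + n]


def _logistic_ramp(n, rise_samples):
    """Logistic 0->1 ramp whose 10-90% rise spans ~``rise_samples``."""
    t = np.arange(n, dtype=float)
    scale = max(rise_samples / 4.4, 1e-6)  # logistic 10-90% width = 4.4*scale
    return 1.0 / (1.0 + np.exp(-(t - rise_samples / 2.0) / scale))


def generate_recording(
    seq: MotionSequence | Iterable[str],
    profile: UserProfile,
    *,
    sample_rate: float = 100.0,
    rng: Optional[np.random.Generator] = None,
) -> EOGRecording:
    """Render a motion sequence as a labelled six-channel EOG recording.

    The label track covers the whole signal, including the "sil" padding
    segments.  Repeated calls with the same profile seed (and no
    external ``rng``) are bit-identical.
    """
    if not isinstance(seq, MotionSequence):
        seq = MotionSequence(seq)
    if len(seq) == 0:
        raise ValueError("motion sequence is empty")
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    fs = sample_rate
    min_dur = profile.rise_time + 0.05
    segments: list[tuple[str, int]] = []
    if profile.sil_duration > 0:
        segments.append((SIL, max(1, round(profile.sil_duration * fs))))
    for m in seq:
        dur = rng.normal(profile.motion_duration_mean, profile.motion_duration_std)
        dur = max(dur, min_dur)
        segments.append((m, max(1, round(dur * fs))))
    if profile.sil_duration > 0:
        segments.append((SIL, max(1, round(profile.sil_duration * fs))))

    total = sum(n for _, n in segments)
    gaze = np.empty((total, 2))
    pos = np.zeros(2)
    rise_samples = profile.rise_time * fs
    offset = 0
    labels = []
    for lab, n in segments:
        target = np.asarray(GAZE_TARGETS[lab])
        if lab == SIL:
            # no saccade: hold current position (center) without a ramp
            traj = np.repeat(pos[None, :], n, axis=0)
        else:
            if profile.gain_jitter_std > 0:
                target = target * rng.normal(1.0, profile.gain_jitter_std)
            ramp = _logistic_ramp(n, rise_samples)
            traj = pos[None, :] + (target - pos)[None, :] * ramp[:, None]
        gaze[offset : offset + n] = traj
        pos = traj[-1].copy()
        labels.append((offset, offset + n, lab))
        offset += n

    geometry = CHANNEL_GEOMETRY
    if profile.geometry_jitter > 0:
        g_rng = np.random.default_rng(profile.geometry_seed)
        geometry = geometry + (profile.geometry_jitter * _GEOMETRY_SCALE
                               * g_rng.standard_normal((6, 2)))
    eog = profile.amplitude_scale * gaze @ geometry.T
    if profile.drift_rate > 0:
        incr = rng.normal(0.0, profile.drift_rate / np.sqrt(fs), size=(total, 6))
        eog = eog + np.cumsum(incr, axis=0)
    eog = eog + _band_limited_noise(rng, total, 6, profile.noise_std, fs)
    return EOGRecording(samples=eog, sample_rate=fs, labels=labels)


def random_motion_sequence(length: int, rng: np.random.Generator) -> MotionSequence:
    """Uniform random sequence under the no-adjacent-repeat constraint."""
    if length < 1:
        raise ValueError("length must be >= 1")
    motions = [MOTIONS[rng.integers(len(MOTIONS))]]
    for _ in range(length - 1):
        choices = [m for m in MOTIONS if m != motions[-1]]
        motions.append(choices[rng.integers(len(choices))])
    return MotionSequence(motions)


def generate_corpus(
    n_sequences: int,
    profile: UserProfile,
    length_range: tuple[int, int] = (4, 8),
    *,
    sample_rate: float = 100.0,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[MotionSequence, EOGRecording]]:
    """Generate ``n_sequences`` random labelled recordings.

    Sequence lengths are sampled uniformly from ``length_range``
    (inclusive); the default 4-8 motions matches typical training
    sequence lengths for this task.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    out = []
    for _ in range(n_sequences):
        length = int(rng.integers(lo, hi + 1))
        seq = random_motion_sequence(length, rng)
        out.append((seq, generate_recording(seq, profile, sample_rate=sample_rate, rng=rng)))
    return out


# ---------------------------------------------------------------------------
# Plain-text I/O: CSV samples + TSV labels + JSON metadata sidecars.

def write_recording(
    rec: EOGRecording,
    base: str | Path,
    profile: Optional[UserProfile] = None,
    extra_meta: Optional[dict] = None,
) -> None:
    """Write ``base.csv`` (CH1..CH6), ``base.labels.tsv``, ``base.meta.json``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(f"CH{i+1}" for i in range(rec.n_channels))
    np.savetxt(base.with_suffix(".csv"), rec.samples, delimiter=",",
               header=header, comments="", fmt="%.6f")
    if rec.labels is not None:
        with open(base.with_suffix(".labels.tsv"), "w") as fh:
            fh.write("start_sample\tend_sample\tmotion\n")
            for s, e, lab in rec.labels:
                fh.write(f"{s}\t{e}\t{lab}\n")
    meta = {
        "format": "eogdeco-recording",
        "version": 1,
        "sample_rate": rec.sample_rate,
        "n_samples": len(rec),
        "n_channels": rec.n_channels,
    }
    if profile is not None:
        meta["profile"] = asdict(profile)
    if extra_meta:
        meta.update(extra_meta)
    base.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_recording(base: str | Path) -> EOGRecording:
    """Read a recording written by :func:`write_recording`."""
    base = Path(base)
    csv = base.with_suffix(".csv")
    if not csv.exists():
        raise FileNotFoundError(str(csv))
    samples = np.loadtxt(csv, delimiter=",", skiprows=1, ndmin=2)
    meta_path = base.with_suffix(".meta.json")
    sample_rate = 100.0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        sample_rate = float(meta["sample_rate"])
        if meta.get("n_samples") != len(samples):
            raise ValueError(f"{csv}: sample count does not match metadata")
    labels = None
    lab_path = base.with_suffix(".labels.tsv")
    if lab_path.exists():
        labels = []
        with open(lab_path) as fh:
            head = fh.readline().strip().split("\t")
            if head != ["start_sample", "end_sample", "motion"]:
                raise ValueError(f"{lab_path}: bad label header {head}")
            for line in fh:
                s, e, lab = line.rstrip("\n").split("\t")
                labels.append((int(s), int(e), lab))
    return EOGRecording(samples=samples, sample_rate=sample_rate, labels=labels)
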