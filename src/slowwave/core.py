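"""Core data containers for slow-wave recordings.

A recording is represented by one or more uniformly sampled :class:`Trace`
objects (LFP, membrane potential, raw extracellular signal), point-process
:class:`SpikeTrain` objects, and a :class:`StateSegmentation` labelling the
recording as alternating up / down / indeterminate periods.

Conventions
-----------
* Angles are degrees in ``[0, 360)`` at every public interface.
* Sample ``i`` of a trace covers the half-open time interval
  ``[t0 + i/fs, t0 + (i+1)/fs)``; spikes are assigned to samples and to
  state intervals with the same half-open rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Trace",
    "SpikeTrain",
    "Interval",
    "StateSegmentation",
    "PhaseTrace",
    "UP",
    "DOWN",
    "INDETERMINATE",
]

UP = "up"
DOWN = "down"
INDETERMINATE = "indeterminate"
_LABELS = (UP, DOWN, INDETERMINATE)


@dataclass
class Trace:
    """Uniformly sampled continuous signal.

    Parameters
    ----------
    samples : array-like
        Signal values.
    fs : float
        Sampling rate in Hz, > 0.
    units : str
        Physical units of the samples ("mV", "uV", "a.u.", "deg/s", ...).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def index_at(self, t) -> np.ndarray:
        """Sample index containing time ``t`` (half-open convention)."""
        idx = np.floor((np.asarray(t, dtype=float) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, self.samples.size - 1)

    def copy_with(self, **kw) -> "Trace":
        return replace(self, **kw)


@dataclass
class PhaseTrace(Trace):
    """Instantaneous phase in degrees in ``[0, 360)``.

    ``0`` deg marks the peak of the band-passed signal and ``180`` deg its
    trough; with the LFP polarity used throughout the package, troughs (and
    hence phases near 180 deg) correspond to up states.
    """

    band: tuple = (0.1, 4.0)
    method: str = "hilbert"

    def __post_init__(self):
        super().__post_init__()
        self.units = "deg"
        self.samples = np.mod(self.samples, 360.0)

    @property
    def phase(self) -> np.ndarray:
        return self.samples


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell, in seconds."""

    times: np.ndarray
    cell_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Interval:
    """Labelled time interval ``[onset, offset)``."""

    onset: float
    offset: float
    label: str

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError(f"offset must exceed onset ({self.onset}, {self.offset})")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset


@dataclass
class StateSegmentation:
    """Ordered, non-overlapping intervals covering a recording."""

    intervals: list = field(default_factory=list)

    def __post_init__(self):
        iv = sorted(self.intervals, key=lambda i: i.onset)
        for a, b in zip(iv[:-1], iv[1:]):
            if b.onset < a.offset - 1e-12:
                raise ValueError("intervals overlap")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def t0(self) -> float:
        return self.intervals[0].onset

    @property
    def t_end(self) -> float:
        return self.intervals[-1].offset

    def of_label(self, label: str) -> list:
        return [iv for iv in self.intervals if iv.label == label]

    def label_at(self, t) -> np.ndarray:
        """Label of the interval containing each time in ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        onsets = np.array([iv.onset for iv in self.intervals])
        idx = np.searchsorted(onsets, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.intervals) - 1)
        out = np.array([self.intervals[i].label for i in idx], dtype=object)
        # times past the final offset are outside the segmentation
        out[t >= self.t_end + 1e-12] = INDETERMINATE
        out[t < self.t0 - 1e-12] = INDETERMINATE
        return out

    def sample_labels(self, n: int, fs: float, t0: float = 0.0) -> np.ndarray:
        """Per-sample labels for a trace of ``n`` samples at ``fs`` Hz."""
        times = t0 + np.arange(n) / fs
        return self.label_at(times)

    def interval_index_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        onsets = np.array([iv.onset for iv in self.intervals])
        idx = np.searchsorted(onsets, t, side="right") - 1
        return np.clip(idx, 0, len(self.intervals) - 1)


def segmentation_from_labels(labels: Sequence[str], fs: float, t0: float = 0.0) -> StateSegmentation:
    """Build a segmentation from per-sample labels (run-length encoding)."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label array")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    ivs = [
        Interval(t0 + s / fs, t0 + e / fs, str(labels[s]))
        for s, e in zip(starts, ends)
    ]
    return StateSegmentation(ivs)
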