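"""Core data containers for UP-DOWN state (UDS) segmentation.

The pipeline moves between three representations of a recording:

* :class:`SignalRecording` -- the raw sampled trace(s) at acquisition rate;
* :class:`ObservationSequence` -- derived signal features at a (usually lower)
  feature sampling rate, organised as possibly discontinuous segments;
* :class:`StateSequence` -- the decoded alternating UP/DOWN labelling, stored
  both as per-sample labels and as the list of transition times.

States are labelled ``DOWN = 0`` and ``UP = 1`` throughout; for LFP input the
signal is inverted beforehand so that UP states are positive deflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DOWN = 0
UP = 1

_CHANNEL_KINDS = ("LFP", "EEG", "MP")


@dataclass
class SignalRecording:
    """A continuously sampled single- or multi-channel recording.

    Parameters
    ----------
    samples : ndarray, shape (T,) or (T, C)
        Sampled signal, arbitrary units (e.g. microvolts).
    fs : float
        Sampling rate in Hz.
    channel_kind : {"LFP", "EEG", "MP"}
        Signal class; LFP traces are conventionally inverted so UP is positive.
    inverted : bool
        Whether the samples have (already) been negated exactly once.
    """

    samples: np.ndarray
    fs: float
    channel_kind: str = "LFP"
    inverted: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.channel_kind not in _CHANNEL_KINDS:
            raise ValueError(f"channel_kind must be one of {_CHANNEL_KINDS}")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")
        if self.samples.ndim == 2 and len({len(c) for c in self.samples.T}) > 1:
            raise ValueError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, i: int = 0) -> np.ndarray:
        """Return channel ``i`` as a 1-D array."""
        if self.samples.ndim == 1:
            if i != 0:
                raise IndexError("single-channel recording")
            return self.samples
        return self.samples[:, i]

    def invert(self) -> "SignalRecording":
        """Return a copy with negated samples and the ``inverted`` flag toggled."""
        return SignalRecording(-self.samples, self.fs, self.channel_kind,
                               not self.inverted)


class SegmentSet:
    """Sorted, non-overlapping half-open ``[start, end)`` sample intervals.

    Used both for retained-epoch bookkeeping on the raw sample axis and for
    the discontinuous-segment structure of an :class:`ObservationSequence`.
    """

    def __init__(self, intervals: Sequence[Sequence[int]], fs: float):
        arr = np.asarray(intervals, dtype=int).reshape(-1, 2)
        if arr.size:
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("each interval must satisfy end > start")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("intervals must be non-overlapping")
        self.intervals = arr
        self.fs = float(fs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"SegmentSet({self.intervals.tolist()}, fs={self.fs})"

    @property
    def total_samples(self) -> int:
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def lengths(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def to_seconds(self) -> np.ndarray:
        """Return intervals as a float array of (start_s, end_s) rows."""
        return self.intervals / self.fs

    def covers(self) -> np.ndarray:
        """Boolean mask over ``[0, max_end)`` marking covered samples."""
        n = int(self.intervals[:, 1].max()) if len(self) else 0
        mask = np.zeros(n, dtype=bool)
        for s, e in self.intervals:
            mask[s:e] = True
        return mask

    def rescale(self, out_fs: float, n_out: int | None = None) -> "SegmentSet":
        """Map the intervals onto a grid sampled at ``out_fs``."""
        scale = out_fs / self.fs
        iv = []
        for s, e in self.intervals:
            a, b = int(round(s * scale)), int(round(e * scale))
            if n_out is not None:
                b = min(b, n_out)
            if b > a:
                iv.append((a, b))
        return SegmentSet(iv, out_fs)

    @classmethod
    def whole(cls, n_samples: int, fs: float) -> "SegmentSet":
        return cls([(0, n_samples)], fs)


class ObservationSequence:
    """Feature vectors per time step, organised as discontinuous segments.

    ``features`` is a T x D matrix whose rows are the concatenation of the
    samples inside ``segment_map``'s intervals (stated on the feature grid,
    i.e. interval indices address the *uncut* feature axis).
    """

    def __init__(self, features: np.ndarray, fs: float,
                 segment_map: SegmentSet | None = None):
        f = np.asarray(features, dtype=float)
        if f.ndim == 1:
            f = f[:, None]
        if f.ndim != 2 or f.shape[1] < 1:
            raise ValueError("features must be T x D with D >= 1")
        if not np.all(np.isfinite(f)):
            raise ValueError("features must be finite")
        if segment_map is None:
            segment_map = SegmentSet.whole(f.shape[0], fs)
        if segment_map.total_samples != f.shape[0]:
            raise ValueError("segment_map must account for every feature row")
        self.features = f
        self.fs = float(fs)
        self.segment_map = segment_map

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_segments(self) -> int:
        return len(self.segment_map)

    def segment_slices(self) -> list[slice]:
        """Row slices of ``features`` corresponding to each segment."""
        out, pos = [], 0
        for s, e in self.segment_map:
            out.append(slice(pos, pos + (e - s)))
            pos += e - s
        return out

    def segment_features(self) -> list[np.ndarray]:
        return [self.features[sl] for sl in self.segment_slices()]

    def squeezed(self) -> np.ndarray:
        """Features as a 1-D array (requires D == 1)."""
        if self.n_features != 1:
            raise ValueError("observation sequence is not scalar")
        return self.features[:, 0]


@dataclass
class StateSequence:
    """Alternating UP/DOWN labelling of one or more segments.

    Each segment is stored as an array of per-sample labels (0 = DOWN,
    1 = UP); transition times are derived and cached.  ``segment_map``
    (optional) states where each segment lives on the uncut sample axis.
    """

    labels: list[np.ndarray]
    fs: float
    segment_map: SegmentSet | None = None
    _transitions: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = [np.asarray(l, dtype=int) for l in self.labels]
        for l in self.labels:
            if l.size and not np.isin(l, (DOWN, UP)).all():
                raise ValueError("labels must be 0 (DOWN) or 1 (UP)")
        self._transitions = None

    @classmethod
    def from_labels(cls, labels, fs: float,
                    segment_map: SegmentSet | None = None) -> "StateSequence":
        if isinstance(labels, np.ndarray) and labels.ndim == 1:
            labels = [labels]
        return cls(list(labels), fs, segment_map)

    @property
    def n_segments(self) -> int:
        return len(self.labels)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.labels) if self.labels else np.empty(0, int)

    def transitions(self, segment: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Transition sample indices and entered-state labels for a segment.

        Index ``t`` in the result means the state changes between samples
        ``t-1`` and ``t`` (the entered state starts at sample ``t``),
        indices local to the segment.
        """
        lab = self.labels[segment]
        idx = np.flatnonzero(np.diff(lab)) + 1
        return idx, lab[idx]

    def intervals(self, segment: int = 0) -> list[tuple[int, int, int]]:
        """(state, start, end) runs for one segment, half-open sample indices."""
        lab = self.labels[segment]
        if lab.size == 0:
            return []
        idx, _ = self.transitions(segment)
        bounds = np.concatenate(([0], idx, [lab.size]))
        return [(int(lab[bounds[i]]), int(bounds[i]), int(bounds[i + 1]))
                for i in range(len(bounds) - 1)]

    def durations(self, state: int, exclude_boundary: bool = False) -> np.ndarray:
        """Dwell lengths (in samples) of ``state`` pooled over segments.

        With ``exclude_boundary`` the first and last run of every segment are
        dropped: their lengths are censored by the segment edges.
        """
        out = []
        for seg in range(self.n_segments):
            runs = self.intervals(seg)
            if exclude_boundary:
                runs = runs[1:-1]
            out.extend(e - s for k, s, e in runs if k == state)
        return np.asarray(out, dtype=int)

    def to_frame(self):
        """All state intervals as a DataFrame (state, start_s, end_s)."""
        import pandas as pd

        rows = []
        for seg in range(self.n_segments):
            off = (self.segment_map.intervals[seg, 0]
                   if self.segment_map is not None else 0)
            for k, s, e in self.intervals(seg):
                rows.append({"segment": seg, "state": "UP" if k == UP else "DOWN",
                             "start_s": (s + off) / self.fs,
                             "end_s": (e + off) / self.fs})
        return pd.DataFrame(rows, columns=["segment", "state", "start_s", "end_s"])

    def accuracy(self, other: "StateSequence") -> float:
        """Fraction of samples on which two labelings agree."""
        a, b = self.concatenated(), other.concatenated()
        if a.size != b.size:
            raise ValueError("sequences have different lengths")
        return float(np.mean(a == b))
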