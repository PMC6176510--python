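"""Windowing of multichannel recordings and class-balanced window sampling.

Seizure intervals are cut into consecutive non-overlapping windows; an equal
number of non-seizure windows is drawn around each interval — half (rounded
down) from the region before it, the rest from the region after — so the two
classes balance exactly per interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SEIZURE",
    "NON_SEIZURE",
    "Recording",
    "WindowSet",
    "samples_per_window",
    "segment_seizures",
    "balanced_counts",
    "sample_nonseizure_windows",
    "build_window_set",
]

SEIZURE = 1
NON_SEIZURE = 0


@dataclass
class Recording:
    """A multichannel signal with sampling rate and seizure annotations.

    ``seizure_intervals`` are half-open ``(start_sample, end_sample)`` pairs,
    sorted and non-overlapping, within the signal length.
    """

    signal: np.ndarray
    sampling_rate: float
    seizure_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.seizure_intervals = [(int(s), int(e)) for s, e in self.seizure_intervals]
        prev_end = 0
        for s, e in self.seizure_intervals:
            if s < prev_end:
                raise ValueError("seizure intervals must be sorted, non-overlapping")
            if e <= s or e > self.n_samples:
                raise ValueError("seizure interval outside signal")
            prev_end = e

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class WindowSet:
    """Labelled window starts at a fixed window size (samples)."""

    window_size: int
    entries: list = field(default_factory=list)  # (start_sample, label)

    def starts(self, label: int) -> list:
        return [s for s, lab in self.entries if lab == label]


def samples_per_window(window_seconds: float, sampling_rate: float) -> int:
    """Window length in samples for a duration at a sampling rate."""
    return int(round(window_seconds * sampling_rate))


def segment_seizures(recording: Recording, window_size: int) -> list:
    """Per seizure interval, the starts of its consecutive non-overlapping
    windows: floor(interval_length / window_size) windows from the interval
    start (an interval shorter than one window yields none)."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    out = []
    for s, e in recording.seizure_intervals:
        count = (e - s) // window_size
        out.append([s + i * window_size for i in range(count)])
    return out


def balanced_counts(seizure_length: int, window_size: int) -> tuple[int, int, int]:
    """(count_seizure, count_prior, count_posterior) for one seizure interval.

    count_seizure = floor(length / window); count_prior = floor(length / 2 /
    window); count_posterior makes the non-seizure total equal the seizure
    total.
    """
    if seizure_length < 1 or window_size < 1:
        raise ValueError("sizes must be positive")
    count_seizure = seizure_length // window_size
    count_prior = seizure_length // (2 * window_size)
    return count_seizure, count_prior, count_seizure - count_prior


def _place_uniform(
    lo: int, hi: int, count: int, window_size: int, rng: np.random.Generator
) -> list:
    """``count`` non-overlapping window starts uniformly placed in [lo, hi).

    Draws the free slack uniformly and stacks windows left to right, which
    samples uniformly over all non-overlapping configurations without
    rejection.
    """
    if count == 0:
        return []
    slack = (hi - lo) - count * window_size
    offsets = np.sort(rng.integers(0, slack + 1, size=count))
    return [int(lo + offsets[i] + i * window_size) for i in range(count)]


def sample_nonseizure_windows(
    recording: Recording,
    window_size: int,
    seed: int,
    per_interval_counts: Sequence[tuple] = None,
) -> list:
    """Non-seizure window starts balancing the seizure windows.

    For each seizure interval, ``count_prior`` windows are drawn from the
    stretch between the previous interval (or the recording start) and the
    interval, and ``count_posterior`` from the stretch up to the next interval
    (or the recording end).  Placement is uniform over non-overlapping
    configurations and deterministic for a fixed seed.

    Raises ``ValueError`` naming the interval if a stretch cannot hold its
    requested windows.
    """
    rng = np.random.default_rng(seed)
    intervals = recording.seizure_intervals
    if per_interval_counts is None:
        per_interval_counts = [
            balanced_counts(e - s, window_size)[1:] for s, e in intervals
        ]
    starts: list = []
    for idx, ((s, e), (n_prior, n_post)) in enumerate(
        zip(intervals, per_interval_counts)
    ):
        prev_end = intervals[idx - 1][1] if idx > 0 else 0
        next_start = (
            intervals[idx + 1][0] if idx + 1 < len(intervals) else recording.n_samples
        )
        if (s - prev_end) < n_prior * window_size:
            raise ValueError(
                f"seizure interval {idx} ({s}, {e}): insufficient non-seizure "
                f"room before it for {n_prior} windows"
            )
        if (next_start - e) < n_post * window_size:
            raise ValueError(
                f"seizure interval {idx} ({s}, {e}): insufficient non-seizure "
                f"room after it for {n_post} windows"
            )
        starts.extend(_place_uniform(prev_end, s, n_prior, window_size, rng))
        starts.extend(_place_uniform(e, next_start, n_post, window_size, rng))
    return starts


def build_window_set(recording: Recording, window_size: int, seed: int) -> WindowSet:
    """Balanced labelled window set: all seizure windows plus an equal number
    of sampled non-seizure windows."""
    entries = []
    for interval_starts in segment_seizures(recording, window_size):
        entries.extend((s, SEIZURE) for s in interval_starts)
    for s in sample_nonseizure_windows(recording, window_size, seed):
        entries.append((s, NON_SEIZURE))
    return WindowSet(window_size=window_size, entries=entries)
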