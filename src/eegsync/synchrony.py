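"""Mutual information between channel pairs on amplitude partitions, and the
per-window synchronization matrix built from all pairs.

All entropies are base-2 (bits), estimated from raw empirical frequencies with
no smoothing.  Discretization uses half-open lower-inclusive bins: a value
equal to a cut point joins the upper bin, and out-of-range values clamp to the
first/last bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from eegsync.partitioning import (
    APConfig,
    PartitionScheme,
    ap_cluster,
    equalize_partition_counts,
    partitions_from_labels,
    uniform_partition,
)

__all__ = [
    "JointDistribution",
    "SyncMatrix",
    "discretize",
    "estimate_joint",
    "entropies",
    "mutual_information",
    "apcpmi_pair",
    "uniform_mi_pair",
    "build_cmapcpmi",
    "channel_scheme",
    "self_entropy",
    "partition_sweep",
]


@dataclass
class JointDistribution:
    """Empirical joint probability table for a discretized channel pair."""

    table: np.ndarray
    marginal_x: np.ndarray
    marginal_y: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        self.marginal_x = np.asarray(self.marginal_x, dtype=float)
        self.marginal_y = np.asarray(self.marginal_y, dtype=float)
        if self.table.ndim != 2:
            raise ValueError("table must be 2-D")
        if np.any(self.table < 0):
            raise ValueError("negative probability")
        if abs(self.table.sum() - 1.0) > 1e-9:
            raise ValueError("table must sum to 1")
        if not np.allclose(self.marginal_x, self.table.sum(axis=1), atol=1e-9):
            raise ValueError("marginal_x inconsistent with table")
        if not np.allclose(self.marginal_y, self.table.sum(axis=0), atol=1e-9):
            raise ValueError("marginal_y inconsistent with table")

    @classmethod
    def from_table(cls, table: np.ndarray) -> "JointDistribution":
        t = np.asarray(table, dtype=float)
        return cls(table=t, marginal_x=t.sum(axis=1), marginal_y=t.sum(axis=0))

    def transpose(self) -> "JointDistribution":
        return JointDistribution(
            table=self.table.T,
            marginal_x=self.marginal_y,
            marginal_y=self.marginal_x,
        )


@dataclass
class SyncMatrix:
    """Symmetric per-window synchronization matrix.

    Entry (i, j) is the adaptive-partition mutual information between channels
    i and j in bits; the diagonal carries each channel's self-entropy under
    its own partition scheme.  Flattened row-major, this is the classifier's
    feature vector (23 channels -> 529 features).
    """

    values: np.ndarray
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be square")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[0])]
        if len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


def discretize(values: Sequence[float], scheme: PartitionScheme) -> np.ndarray:
    """Map amplitudes to partition indices.

    A value equal to a cut point goes to the upper bin; values outside the
    scheme's range clamp to the first/last partition.
    """
    return np.searchsorted(scheme.boundaries, np.asarray(values, dtype=float),
                           side="right")


def estimate_joint(
    symbols_x: Sequence[int], symbols_y: Sequence[int], kX: int, kY: int
) -> JointDistribution:
    """Empirical joint distribution of two equal-length symbol sequences."""
    sx = np.asarray(symbols_x, dtype=int)
    sy = np.asarray(symbols_y, dtype=int)
    if sx.shape != sy.shape:
        raise ValueError("symbol sequences must have equal length")
    if sx.size == 0:
        raise ValueError("empty symbol sequences")
    counts = np.bincount(sx * kY + sy, minlength=kX * kY).reshape(kX, kY)
    return JointDistribution.from_table(counts / sx.size)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropies(joint: JointDistribution) -> tuple[float, float, float]:
    """(H(X), H(Y), H(X,Y)) in bits, with 0*log(0) taken as 0."""
    return (
        _entropy(joint.marginal_x),
        _entropy(joint.marginal_y),
        _entropy(joint.table.reshape(-1)),
    )


def mutual_information(joint: JointDistribution) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y) in bits (tiny negative rounding -> 0)."""
    h_x, h_y, h_xy = entropies(joint)
    return max(h_x + h_y - h_xy, 0.0)


def apcpmi_pair(
    x: Sequence[float],
    y: Sequence[float],
    scheme_x: PartitionScheme,
    scheme_y: PartitionScheme,
) -> float:
    """Adaptive-partition MI between two channels, in bits.

    The two schemes are first brought to a common partition count (closest
    adjacent partitions of the finer scheme merged), then both channels are
    discretized and the empirical MI is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channels must have equal length")
    sx, sy = equalize_partition_counts(scheme_x, scheme_y)
    joint = estimate_joint(discretize(x, sx), discretize(y, sy), sx.count, sy.count)
    return mutual_information(joint)


def uniform_mi_pair(x: Sequence[float], y: Sequence[float], k: int) -> float:
    """Baseline MI with equal-probability (quantile) partitions, in bits."""
    sx = uniform_partition(x, k)
    sy = uniform_partition(y, k)
    joint = estimate_joint(discretize(x, sx), discretize(y, sy), sx.count, sy.count)
    return mutual_information(joint)


def channel_scheme(values: Sequence[float], config: APConfig) -> PartitionScheme:
    """AP partition scheme of one channel window (values sorted internally)."""
    v = np.sort(np.asarray(values, dtype=float))
    result = ap_cluster(v, config)
    return partitions_from_labels(v, result.labels)


def self_entropy(values: Sequence[float], scheme: PartitionScheme) -> float:
    """H(X) of a channel under a partition scheme, in bits."""
    symbols = discretize(values, scheme)
    counts = np.bincount(symbols, minlength=scheme.count)
    return _entropy(counts / counts.sum())


def build_cmapcpmi(
    window: np.ndarray,
    channel_names: Union[Sequence[str], None] = None,
    config: APConfig = APConfig(),
) -> SyncMatrix:
    """Synchronization matrix of one channels x samples window.

    Affinity propagation runs once per channel; the resulting schemes are
    reused for all pairs.  The matrix is symmetric with per-channel
    self-entropies on the diagonal.  A constant channel yields a single
    partition, hence zero MI with every other channel.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be channels x samples")
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels")

    schemes = [channel_scheme(w[i], config) for i in range(n)]
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = self_entropy(w[i], schemes[i])
    for i in range(n):
        for j in range(i + 1, n):
            mi = apcpmi_pair(w[i], w[j], schemes[i], schemes[j])
            values[i, j] = mi
            values[j, i] = mi
    names = list(channel_names) if channel_names is not None else None
    return SyncMatrix(values=values, channel_names=names or [])


@dataclass
class SweepResult:
    """Per-bin-count summary of the uniform-partition MI baseline."""

    k: int
    mean_matrix: np.ndarray
    average_std: float


def partition_sweep(
    windows: Sequence[np.ndarray], k_list: Sequence[int]
) -> list[SweepResult]:
    """Uniform-partition MI matrices across windows for each bin count.

    For each ``k``: every window's full MI matrix (diagonal = self-entropy at
    ``k`` quantile bins), the element-wise mean matrix, and the element-wise
    standard deviation across windows averaged over all matrix entries.
    """
    results = []
    for k in k_list:
        mats = []
        for w in windows:
            w = np.asarray(w, dtype=float)
            n = w.shape[0]
            m = np.zeros((n, n))
            schemes = [uniform_partition(w[i], k) for i in range(n)]
            for i in range(n):
                m[i, i] = self_entropy(w[i], schemes[i])
            for i in range(n):
                for j in range(i + 1, n):
                    joint = estimate_joint(
                        discretize(w[i], schemes[i]),
                        discretize(w[j], schemes[j]),
                        schemes[i].count,
                        schemes[j].count,
                    )
                    m[i, j] = m[j, i] = mutual_information(joint)
            mats.append(m)
        stack = np.stack(mats)
        results.append(
            SweepResult(
                k=int(k),
                mean_matrix=stack.mean(axis=0),
                average_std=float(stack.std(axis=0).mean()),
            )
        )
    return results
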