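"""Amplitude partitioning of a single channel window.

Affinity propagation (AP) clusters the (sorted) amplitude values of one
channel; each cluster becomes an amplitude partition described by its center
and radius, and cut points between adjacent partitions sit at the midpoint of
the empty gap separating them.  An equal-probability quantile partitioner is
provided as the conventional baseline.

AP is implemented here rather than borrowed: the message-passing runs without
noise injection and with a fixed tie-break (lower sample index wins) so that
two runs on identical input are bit-identical, which library versions do not
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "APConfig",
    "APResult",
    "Partition",
    "PartitionScheme",
    "compute_similarity",
    "ap_cluster",
    "partitions_from_labels",
    "equalize_partition_counts",
    "uniform_partition",
    "merge_adjacent",
    "scheme_from_partitions",
]


@dataclass(frozen=True)
class APConfig:
    """Settings for affinity propagation on a 1-D amplitude sequence.

    Parameters
    ----------
    preference
        Diagonal of the similarity matrix (the "reference degree"): either a
        number in similarity units or the token ``"median"``, which resolves
        to the median of the off-diagonal similarities.  Larger values yield
        more exemplars, hence more partitions.
    damping
        Message damping factor in ``[0.5, 1)``.
    max_iter
        Hard cap on message-passing sweeps.
    convergence_iter
        Number of consecutive sweeps with an unchanged exemplar set required
        to declare convergence.
    max_points
        Optional cap on the number of points fed to the message passing.  When
        set and the window is larger, evenly spaced order statistics are
        clustered and the remaining points are assigned through the learned
        partition boundaries.  ``None`` (default) clusters every point.
    """

    preference: Union[float, str] = "median"
    damping: float = 0.5
    max_iter: int = 200
    convergence_iter: int = 15
    max_points: Union[int, None] = None

    def __post_init__(self) -> None:
        if isinstance(self.preference, str) and self.preference != "median":
            raise ValueError(
                f"preference must be a number or 'median', got {self.preference!r}"
            )
        if not 0.5 <= self.damping < 1.0:
            raise ValueError(f"damping must be in [0.5, 1), got {self.damping}")
        if self.convergence_iter < 1:
            raise ValueError("convergence_iter must be >= 1")
        if self.max_iter < self.convergence_iter:
            raise ValueError("max_iter must be >= convergence_iter")
        if self.max_points is not None and self.max_points < 2:
            raise ValueError("max_points must be >= 2 when set")


@dataclass
class APResult:
    """Outcome of one affinity propagation run.

    ``labels[i]`` indexes into ``exemplars`` (ascending exemplar order);
    every exemplar is an actual input value.
    """

    labels: np.ndarray
    exemplars: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


@dataclass(frozen=True)
class Partition:
    """One amplitude partition: extent ``[z_min, z_max]``, center, radius."""

    z_min: float
    z_max: float
    center: float
    radius: float

    def __post_init__(self) -> None:
        if self.z_min > self.z_max:
            raise ValueError("z_min must be <= z_max")


def _make_partition(z_min: float, z_max: float) -> Partition:
    return Partition(
        z_min=float(z_min),
        z_max=float(z_max),
        center=(float(z_max) + float(z_min)) / 2.0,
        radius=abs(float(z_max) - float(z_min)) / 2.0,
    )


@dataclass
class PartitionScheme:
    """Ordered, non-overlapping amplitude partitions for one channel window.

    ``boundaries`` holds ``count - 1`` strictly increasing cut points; each
    cut lies strictly inside the gap between two consecutive partitions.
    """

    partitions: list = field(default_factory=list)
    boundaries: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.boundaries) != max(len(self.partitions) - 1, 0):
            raise ValueError("boundary count must be partition count - 1")
        if len(self.boundaries) > 1 and not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.partitions)


def compute_similarity(values: Sequence[float], config: APConfig) -> np.ndarray:
    """Negated squared Euclidean distance table with the preference on the
    diagonal.

    Larger entries mean more similar, the convention the message passing
    requires; the resolved ``"median"`` preference is the median of the
    off-diagonal entries (0.0 for a single point, which has none).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if v.size == 0:
        raise ValueError("empty window")
    diff = v[:, None] - v[None, :]
    sim = -(diff * diff)
    pref = _resolve_preference(sim, config.preference)
    np.fill_diagonal(sim, pref)
    return sim


def _resolve_preference(sim: np.ndarray, preference: Union[float, str]) -> float:
    if not isinstance(preference, str):
        return float(preference)
    n = sim.shape[0]
    if n == 1:
        return 0.0
    off = sim[~np.eye(n, dtype=bool)]
    return float(np.median(off))


def ap_cluster(values: Sequence[float], config: APConfig = APConfig()) -> APResult:
    """Cluster sorted 1-D amplitudes with affinity propagation.

    Alternates the responsibility and availability updates with damping until
    the exemplar set is unchanged for ``config.convergence_iter`` sweeps or
    ``config.max_iter`` is reached.  Deterministic: no noise is added to the
    similarities and argmax ties resolve to the lower index.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty window")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in window")
    if np.any(np.diff(v) < 0):
        raise ValueError("values must be sorted ascending")

    if config.max_points is not None and v.size > config.max_points:
        return _ap_cluster_subsampled(v, config)

    if v.size == 1:
        return APResult(
            labels=np.zeros(1, dtype=int),
            exemplars=v.copy(),
            n_iter=0,
            converged=True,
        )

    S = compute_similarity(v, config)
    n = S.shape[0]
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    lam = config.damping
    idx = np.arange(n)

    prev_exemplars: Union[frozenset, None] = None
    stable = 0
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        # responsibilities: R(i,k) <- S(i,k) - max_{k' != k} (A(i,k') + S(i,k'))
        AS = A + S
        first_k = np.argmax(AS, axis=1)
        first_v = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second_v = np.max(AS, axis=1)
        Rnew = S - first_v[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second_v
        R = lam * R + (1.0 - lam) * Rnew

        # availabilities: A(i,k) <- min(0, R(k,k) + sum_{i' not in {i,k}} max(0, R(i',k)))
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, 0.0)
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, R[idx, idx][None, :] + col[None, :] - Rp)
        Anew[idx, idx] = col  # A(k,k) = sum of positive responsibilities to k
        A = lam * A + (1.0 - lam) * Anew

        exemplars = frozenset(np.flatnonzero(np.diag(R) + np.diag(A) > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= config.convergence_iter:
                converged = True
                break
        else:
            stable = 1 if exemplars else 0
        prev_exemplars = exemplars if exemplars else None

    exemplar_idx = np.flatnonzero(np.diag(R) + np.diag(A) > 0)
    if exemplar_idx.size == 0:
        # degenerate (e.g. all-identical values): fall back to the single best
        # candidate; ties resolve to the lowest index via argmax
        exemplar_idx = np.array([int(np.argmax(np.diag(R) + np.diag(A)))])

    labels = np.argmax(S[:, exemplar_idx], axis=1)
    labels[exemplar_idx] = np.arange(exemplar_idx.size)  # exemplars label themselves
    # drop exemplars that attracted no points after the final assignment
    used = np.unique(labels)
    if used.size < exemplar_idx.size:
        remap = -np.ones(exemplar_idx.size, dtype=int)
        remap[used] = np.arange(used.size)
        labels = remap[labels]
        exemplar_idx = exemplar_idx[used]

    order = np.argsort(v[exemplar_idx], kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return APResult(
        labels=rank[labels],
        exemplars=v[exemplar_idx][order],
        n_iter=n_iter,
        converged=converged,
    )


def _ap_cluster_subsampled(v: np.ndarray, config: APConfig) -> APResult:
    """Cluster evenly spaced order statistics, then assign every point through
    the learned partition boundaries."""
    take = np.linspace(0, v.size - 1, config.max_points).round().astype(int)
    sub = ap_cluster(v[take], APConfig(
        preference=config.preference,
        damping=config.damping,
        max_iter=config.max_iter,
        convergence_iter=config.convergence_iter,
    ))
    scheme = partitions_from_labels(v[take], sub.labels)
    labels = np.searchsorted(scheme.boundaries, v, side="right")
    return APResult(
        labels=labels,
        exemplars=sub.exemplars,
        n_iter=sub.n_iter,
        converged=sub.converged,
    )


def scheme_from_partitions(partitions: Sequence[Partition]) -> PartitionScheme:
    """Order partitions by center, validate disjointness, place each cut at the
    midpoint of the gap between consecutive partitions."""
    parts = sorted(partitions, key=lambda p: p.center)
    boundaries = []
    for lo, hi in zip(parts[:-1], parts[1:]):
        if hi.z_min <= lo.z_max:
            raise ValueError("non-separable clusters")
        # half-gap between upper edge of the lower partition and lower edge of
        # the upper one; the cut sits at (upper edge) + half-gap = gap midpoint
        half_gap = ((hi.center - hi.radius) - (lo.center + lo.radius)) / 2.0
        boundaries.append((lo.center + lo.radius) + half_gap)
    return PartitionScheme(partitions=list(parts), boundaries=np.asarray(boundaries))


def partitions_from_labels(
    values: Sequence[float], labels: Sequence[int]
) -> PartitionScheme:
    """Turn a clustering of amplitudes into an ordered partition scheme.

    Each cluster contributes one partition spanning its min..max amplitude;
    clusters whose extents interleave cannot form disjoint amplitude
    partitions and raise ``ValueError("non-separable clusters")``.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have equal length")
    parts = [
        _make_partition(v[lab == k].min(), v[lab == k].max()) for k in np.unique(lab)
    ]
    return scheme_from_partitions(parts)


def merge_adjacent(scheme: PartitionScheme, i: int) -> PartitionScheme:
    """Merge partitions ``i`` and ``i + 1`` into one spanning both extents."""
    parts = list(scheme.partitions)
    merged = _make_partition(parts[i].z_min, parts[i + 1].z_max)
    return scheme_from_partitions(parts[:i] + [merged] + parts[i + 2:])


def equalize_partition_counts(
    scheme_x: PartitionScheme, scheme_y: PartitionScheme
) -> tuple[PartitionScheme, PartitionScheme]:
    """Merge closest adjacent partitions in the larger scheme until the two
    schemes carry the same partition count.

    The scheme with the smaller count is returned unchanged; merging picks
    the adjacent pair with the smallest center-to-center gap, repeatedly.
    Inputs are never mutated.
    """
    sx, sy = scheme_x, scheme_y
    while sx.count != sy.count:
        big = sx if sx.count > sy.count else sy
        centers = np.array([p.center for p in big.partitions])
        i = int(np.argmin(np.diff(centers)))
        big = merge_adjacent(big, i)
        if sx.count > sy.count:
            sx = big
        else:
            sy = big
    return sx, sy


def uniform_partition(values: Sequence[float], k: int) -> PartitionScheme:
    """Equal-probability (quantile) partitioning into ``k`` bins.

    Cut points sit midway between the order statistics flanking each ``i/k``
    quantile; on distinct values the bin occupancies differ by at most one.
    Ties shift cuts to the nearest strict increase so boundaries remain
    strictly increasing; ``k`` must not exceed the number of distinct values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty window")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(v).size
    if k > n_distinct:
        raise ValueError("too many bins")
    n = v.size
    if k == 1:
        return PartitionScheme(partitions=[_make_partition(v[0], v[-1])])

    # positions j where a cut between v[j-1] and v[j] separates distinct values
    gaps = np.flatnonzero(np.diff(v) > 0) + 1
    targets = [n * i / k for i in range(1, k)]
    chosen: list[int] = []
    lo = 0  # index into gaps; each cut must use a later gap than the previous
    for t_i, target in enumerate(targets):
        hi = len(gaps) - (len(targets) - t_i - 1)  # leave room for later cuts
        window = gaps[lo:hi]
        j = int(np.argmin(np.abs(window - target)))
        chosen.append(int(window[j]))
        lo += j + 1

    cuts = np.array(chosen)
    boundaries = (v[cuts - 1] + v[cuts]) / 2.0
    edges = np.concatenate(([0], cuts, [n]))
    parts = [_make_partition(v[a], v[b - 1]) for a, b in zip(edges[:-1], edges[1:])]
    return PartitionScheme(partitions=parts, boundaries=boundaries)
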