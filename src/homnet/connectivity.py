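"""Static and sliding-window dynamic functional-connectivity networks.

The low-order dynamic FC network (LoD-FCN) of a subject is the ordered stack of
Pearson correlation matrices computed on overlapping segments of the ROI time
series: a window of length ``W`` slides in steps of ``s``, giving
``K = floor((M - W) / s) + 1`` windows (a trailing partial segment is
discarded so every window has the same length). The static network (C-FCN) is
the degenerate single-window case ``W = M``.

Undefined correlations (a region constant within a segment) are set to 0 with
a warning rather than propagating NaN; the unit diagonal is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from homnet.data_io import NetworkMatrix, RoiTimeSeries, ValidationError


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Sliding-window parameters: window length ``W`` and step ``s`` (time points)."""

    W: int
    s: int

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValidationError(f"window length W must be >= 1, got {self.W}")
        if self.s < 1:
            raise ValidationError(f"step s must be >= 1, got {self.s}")

    def n_windows(self, n_timepoints: int) -> int:
        """K = floor((M - W) / s) + 1 for M time points."""
        if self.W > n_timepoints:
            raise ValidationError(
                f"window length W={self.W} exceeds series length M={n_timepoints}"
            )
        return (n_timepoints - self.W) // self.s + 1


@dataclass
class DynamicConnectivity:
    """Ordered stack of windowed correlation matrices (the LoD-FCN).

    ``windows`` has shape ``(K, R, R)``; every slice is symmetric with unit
    diagonal and entries in [-1, 1].
    """

    windows: np.ndarray
    spec: SlidingWindowSpec
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.windows.shape[2]:
            raise ValidationError(
                f"windows must have shape (K, R, R), got {self.windows.shape}"
            )

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_regions(self) -> int:
        return self.windows.shape[1]


@dataclass(frozen=True)
class EdgeSeries:
    """The FC time series of one region pair across the K windows."""

    i: int
    j: int
    values: np.ndarray


@dataclass
class RegionPartition:
    """Assignment of every region to exactly one functional system.

    ``assignment`` maps the positional region index to a system label (e.g.
    DMN, EAN, SMN, VN, SBN, CER). ``systems`` lists the labels in first-seen
    order; blocks are reported in that order.
    """

    assignment: tuple[str, ...]

    def __init__(self, assignment) -> None:
        self.assignment = tuple(str(a) for a in assignment)
        if not self.assignment:
            raise ValidationError("empty region partition")

    @property
    def systems(self) -> list[str]:
        seen: list[str] = []
        for a in self.assignment:
            if a not in seen:
                seen.append(a)
        return seen

    def members(self, system: str) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(self.assignment) if a == system], dtype=int)
        if idx.size == 0:
            raise ValidationError(f"empty block {system!r}")
        return idx


def window_segments(n_timepoints: int, spec: SlidingWindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges of the K overlapping segments.

    Segment ``k`` (0-based) covers ``[k*s, k*s + W)``; the trailing partial
    segment, if any, is discarded so all windows share the same length.
    """
    k = spec.n_windows(n_timepoints)
    return [(i * spec.s, i * spec.s + spec.W) for i in range(k)]


def _pearson_matrix(segment: np.ndarray, context: str = "") -> np.ndarray:
    """Pearson correlation of columns with a zero-variance guard.

    Columns with zero variance yield undefined correlations; those entries are
    set to 0 (diagonal stays 1) and a single warning is emitted. The result is
    exactly symmetric and clipped to [-1, 1].
    """
    n, r = segment.shape
    sd = segment.std(axis=0)
    ok = sd > 0.0
    corr = np.zeros((r, r), dtype=float)
    if ok.sum() >= 2:
        sub = np.corrcoef(segment[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    elif ok.sum() == 1:
        corr[ok, ok] = 1.0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant region(s) {context}: undefined "
            "correlations set to 0",
            stacklevel=3,
        )
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return np.clip(corr, -1.0, 1.0)


def build_lodfcn(ts: RoiTimeSeries, spec: SlidingWindowSpec) -> DynamicConnectivity:
    """Build the low-order dynamic FC network of one subject.

    Window ``k`` holds the Pearson correlation of every region pair restricted
    to segment ``k`` of the time series.
    """
    segments = window_segments(ts.n_timepoints, spec)
    windows = np.empty((len(segments), ts.n_regions, ts.n_regions), dtype=float)
    for k, (lo, hi) in enumerate(segments):
        windows[k] = _pearson_matrix(
            ts.values[lo:hi], context=f"in window {k + 1} of {ts.subject_id!r}"
        )
    return DynamicConnectivity(windows=windows, spec=spec, subject_id=ts.subject_id)


def build_cfcn(ts: RoiTimeSeries) -> NetworkMatrix:
    """Static (conventional) FC network: full-length Pearson correlation.

    Identical to the single window of ``build_lodfcn`` with ``W = M``.
    """
    values = _pearson_matrix(ts.values, context=f"over the full series of {ts.subject_id!r}")
    return NetworkMatrix(values=values, kind="static")


def edge_series(dcn: DynamicConnectivity, i: int, j: int) -> EdgeSeries:
    """Extract the FC time series of edge (i, j) across windows (0-based)."""
    r = dcn.n_regions
    if not (0 <= i < r and 0 <= j < r):
        raise IndexError(f"region index ({i}, {j}) out of range for R={r}")
    return EdgeSeries(i=i, j=j, values=dcn.windows[:, i, j].copy())


def block_interaction(net: NetworkMatrix, partition: RegionPartition) -> NetworkMatrix:
    """Average FC between (and within) functional systems.

    Entry (A, B) is the mean of ``net[i, j]`` over regions ``i`` in system A
    and ``j`` in system B; within a system (A = B) self-pairs ``i = j`` are
    excluded. The result is a symmetric block matrix labelled by system.
    """
    if len(partition.assignment) != net.n_regions:
        raise ValidationError(
            f"partition covers {len(partition.assignment)} regions, network has "
            f"{net.n_regions}"
        )
    systems = partition.systems
    block = np.zeros((len(systems), len(systems)), dtype=float)
    for a, sys_a in enumerate(systems):
        ia = partition.members(sys_a)
        for b, sys_b in enumerate(systems[: a + 1]):
            ib = partition.members(sys_b)
            sub = net.values[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    raise ValidationError(
                        f"system {sys_a!r} has a single region; within-block mean undefined"
                    )
                total = sub.sum() - np.trace(sub)
                count = len(ia) * (len(ia) - 1)
            else:
                total = sub.sum()
                count = sub.size
            block[a, b] = block[b, a] = total / count
    return NetworkMatrix(values=block, kind="block", labels=tuple(systems))
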