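"""Central-moment feature networks CM(d) and the RMS baseline.

Each edge of the dynamic FC network carries a length-K series of windowed
correlations. CM(d) summarises that series by its d-th central moment, mapped
back to the correlation scale by a d-th root:

    m_ij(d) = sign(S) * |S|^(1/d),   S = (1/K) * sum_k (rho_ij(k) - mean)^d

with the arithmetic mean substituted at d = 1 (the first central moment is
identically zero). The signed root keeps odd-order moments real and preserves
their skew sign. Moments use the population normalisation 1/K.

These summaries are invariant to the chronological order of the windows. To
make that invariance hold *bitwise* in floating point (not merely up to
rounding), every reduction here first sorts the edge series: sorting
canonicalises the summation order, so any permutation of the windows produces
identical output bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from homnet.connectivity import DynamicConnectivity, SlidingWindowSpec
from homnet.data_io import NetworkMatrix, ValidationError


@dataclass
class MomentNetwork:
    """Order-d central-moment network extracted from a dynamic FC network.

    The diagonal is exact: 1 for d = 1 (the self-correlation series is
    constant 1, whose mean is 1) and 0 for d >= 2 (a constant series has no
    central moments).
    """

    values: np.ndarray
    order_d: int
    spec: SlidingWindowSpec | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"moment network must be square, got {self.values.shape}")
        if self.order_d < 1:
            raise ValidationError(f"moment order must be >= 1, got {self.order_d}")
        diag = np.diag(self.values)
        want = 1.0 if self.order_d == 1 else 0.0
        if not np.all(diag == want):
            raise ValidationError(
                f"CM({self.order_d}) diagonal must be exactly {want}"
            )
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-10:
            raise ValidationError("moment network asymmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def as_network(self) -> NetworkMatrix:
        return NetworkMatrix(values=self.values, kind="cm", order_d=self.order_d)


def _signed_root(s: np.ndarray | float, d: int):
    return np.sign(s) * np.abs(s) ** (1.0 / d)


def central_moment(values: np.ndarray, d: int) -> float:
    """Order-d central-moment feature of one edge's FC series.

    For ``d = 1`` returns the arithmetic mean. For ``d >= 2`` returns the
    signed d-th root of the population central moment. Permutation-invariant
    in the window order (bitwise, via canonical sorting) and, for ``d >= 2``,
    invariant to adding a constant to the series.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("edge series must be a nonempty 1-D array")
    if d < 1:
        raise ValidationError(f"moment order must be >= 1, got {d}")
    mean = x.mean()
    if d == 1:
        return float(mean)
    if x.size < 2:
        raise ValidationError("degenerate window count: need K >= 2 for d >= 2")
    if x[0] == x[-1]:  # constant series: moments are exactly zero
        return 0.0
    s = ((x - mean) ** d).mean()
    return float(_signed_root(s, d))


def rms_edge(values: np.ndarray) -> float:
    """Root-mean-square of one edge's FC series (baseline feature)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValidationError("edge series must be nonempty")
    return float(np.sqrt((x**2).mean()))


def _sorted_windows(dcn: DynamicConnectivity) -> np.ndarray:
    # canonical (ascending) order per edge: makes reductions bitwise
    # independent of the chronological window order
    return np.sort(dcn.windows, axis=0)


def build_cmfcn(dcn: DynamicConnectivity, d: int) -> MomentNetwork:
    """Build the order-d central-moment network CM(d) from a LoD-FCN.

    Entry (i, j) is :func:`central_moment` of the edge (i, j) FC series; the
    diagonal is set exactly per the type invariant. Output is identical for
    any reordering of the windows.
    """
    if d < 1:
        raise ValidationError(f"moment order must be >= 1, got {d}")
    if d >= 2 and dcn.n_windows < 2:
        raise ValidationError(
            f"degenerate window count: CM({d}) needs K >= 2, got K={dcn.n_windows}"
        )
    x = _sorted_windows(dcn)
    mean = x.mean(axis=0)
    if d == 1:
        values = mean
    else:
        s = ((x - mean) ** d).mean(axis=0)
        s[x[0] == x[-1]] = 0.0  # constant edge series: moments exactly zero
        values = _signed_root(s, d)
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 1.0 if d == 1 else 0.0)
    values = np.triu(values) + np.triu(values, 1).T  # enforce exact symmetry
    return MomentNetwork(values=values, order_d=d, spec=dcn.spec, subject_id=dcn.subject_id)


def build_rms_network(dcn: DynamicConnectivity) -> NetworkMatrix:
    """Edgewise RMS of the windowed FC series (comparison baseline).

    The diagonal is 1 (RMS of the constant-1 self-correlation series).
    """
    x = _sorted_windows(dcn)
    values = np.sqrt((x**2).mean(axis=0))
    np.fill_diagonal(values, 1.0)
    values = np.triu(values) + np.triu(values, 1).T
    return NetworkMatrix(values=values, kind="rms")
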