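"""High-order FC networks: correlations between regions' moment profiles.

Row i of CM(d) is the moment profile of region i — how the dynamic FC between
region i and every other region fluctuates (at order d). The high-order
network Ho(d) correlates these profiles pairwise:

    h_ij(d) = corr(m_i(d), m_j(d))

so an edge of Ho(d) is large when two regions' whole patterns of FC
fluctuation co-vary, a second-level interaction that no single low-order edge
expresses. Ho(d) inherits the window-permutation invariance of CM(d).

By default the full rows participate in the correlation, including the
degenerate diagonal entries (a shared constant for d >= 2, which slightly
inflates positive correlations). ``include_diagonal=False`` instead drops
columns i and j from both rows before correlating the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from homnet.connectivity import (
    DynamicConnectivity,
    SlidingWindowSpec,
    _pearson_matrix,
    build_cfcn,
    build_lodfcn,
)
from homnet.data_io import NetworkMatrix, RoiTimeSeries, ValidationError
from homnet.moment_features import MomentNetwork, build_cmfcn, build_rms_network


@dataclass
class HighOrderNetwork:
    """Ho(d): pairwise correlation of CM(d) rows; symmetric, unit diagonal."""

    values: np.ndarray
    order_d: int
    spec: SlidingWindowSpec | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValidationError(f"high-order network must be square, got {self.values.shape}")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValidationError("high-order network diagonal must be exactly 1")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-10:
            raise ValidationError("high-order network asymmetric")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValidationError("high-order correlations outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def as_network(self) -> NetworkMatrix:
        return NetworkMatrix(values=self.values, kind="ho", order_d=self.order_d)


def build_hofcn(cm: MomentNetwork, include_diagonal: bool = True) -> HighOrderNetwork:
    """Build Ho(d) by correlating the rows of CM(d).

    Zero-variance rows (possible when an edge set is constant) correlate as 0
    with a warning, mirroring the low-order convention; the diagonal stays 1.
    """
    r = cm.n_regions
    if r < 3:
        raise ValidationError(f"row correlation needs R >= 3 regions, got R={r}")
    if include_diagonal:
        values = _pearson_matrix(cm.values.T, context=f"among CM({cm.order_d}) rows")
    else:
        values = np.eye(r)
        rows = cm.values
        warned = False
        for i in range(r):
            for j in range(i + 1, r):
                keep = np.ones(r, dtype=bool)
                keep[[i, j]] = False
                a, b = rows[i, keep], rows[j, keep]
                if a.std() == 0.0 or b.std() == 0.0:
                    if not warned:
                        warnings.warn(
                            f"constant CM({cm.order_d}) row: correlations set to 0",
                            stacklevel=2,
                        )
                        warned = True
                    c = 0.0
                else:
                    c = float(np.corrcoef(a, b)[0, 1])
                values[i, j] = values[j, i] = np.clip(c, -1.0, 1.0)
    return HighOrderNetwork(
        values=values, order_d=cm.order_d, spec=cm.spec, subject_id=cm.subject_id
    )


@dataclass
class AllNetworks:
    """Every network derived from one subject at one sliding-window setting."""

    cfcn: NetworkMatrix
    rms: NetworkMatrix
    cm: dict[int, MomentNetwork] = field(default_factory=dict)
    ho: dict[int, HighOrderNetwork] = field(default_factory=dict)
    lodfcn: DynamicConnectivity | None = None


def build_all_networks(
    ts: RoiTimeSeries,
    spec: SlidingWindowSpec,
    orders: list[int] | tuple[int, ...] = (),
    include_diagonal: bool = True,
    keep_lodfcn: bool = False,
) -> AllNetworks:
    """One pass from a subject's time series to all requested networks.

    Builds the LoD-FCN once and derives the C-FCN, the RMS baseline and, for
    every requested order d, CM(d) and Ho(d). Outputs are identical to calling
    the stage functions independently. An empty ``orders`` yields only the
    baselines.
    """
    dcn = build_lodfcn(ts, spec)
    out = AllNetworks(
        cfcn=build_cfcn(ts),
        rms=build_rms_network(dcn),
        lodfcn=dcn if keep_lodfcn else None,
    )
    for d in orders:
        cm = build_cmfcn(dcn, d)
        out.cm[d] = cm
        out.ho[d] = build_hofcn(cm, include_diagonal=include_diagonal)
    return out
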