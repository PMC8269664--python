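"""Reading and writing subject time series, cohort manifests and network matrices.

All on-disk formats are plain delimited text so that intermediate artifacts are
diff-able and language-neutral:

* time series: CSV/TSV, rows = time points, columns = regions, no header;
* manifest: CSV with header ``subject_id,label,path``;
* network matrices: delimited text with a single ``#`` metadata header line
  carrying ``kind``, ``order_d`` and ``R``.

Region indexing is positional: 0-based internally, 1-based in reports. Columns
are never reordered by the readers.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Vocabulary of network kinds carried in matrix file headers.
NETWORK_KINDS = frozenset({"static", "lodfcn_window", "cm", "ho", "block", "rms"})

#: Accepted spellings for the two class labels (case-insensitive).
LABEL_ALIASES = {
    "1": 1,
    "+1": 1,
    "-1": -1,
    "asd": 1,
    "patient": 1,
    "nc": -1,
    "control": -1,
}

SYMMETRY_TOL = 1e-10


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged BOLD matrix (M time points x R regions).

    Parameters
    ----------
    subject_id :
        Identifier used in manifests and file names.
    values :
        Real matrix of shape ``(M, R)``; rows are time points, columns are
        regions. Must be finite with ``M >= 2`` and ``R >= 2``. Constant
        columns are accepted here; undefined correlations are handled where
        they occur, at correlation time.
    repetition_time :
        Optional TR in seconds (metadata only).
    """

    subject_id: str
    values: np.ndarray
    repetition_time: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"time series for {self.subject_id!r} must be 2-D, "
                f"got shape {self.values.shape}"
            )
        m, r = self.values.shape
        if m < 2 or r < 2:
            raise ValidationError(
                f"time series for {self.subject_id!r} needs at least 2 time "
                f"points and 2 regions, got M={m}, R={r}"
            )
        if not np.all(np.isfinite(self.values)):
            t, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value in time series for {self.subject_id!r} at "
                f"row {t + 1}, column {j + 1}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    label: int
    path: Path


@dataclass
class CohortManifest:
    """Cohort listing: unique subject ids, labels in {+1, -1}, file paths."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("empty cohort")
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate subject_id(s) in manifest: {dup}")
        bad = sorted({e.label for e in self.entries} - {1, -1})
        if bad:
            raise ValidationError(f"labels must be +1 or -1, got {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=int)


@dataclass
class NetworkMatrix:
    """A square symmetric network matrix with a provenance kind.

    ``kind`` distinguishes static correlation networks, individual dynamic-FC
    windows, moment networks, high-order networks, block summaries and the RMS
    baseline. ``order_d`` is set for moment-derived kinds. ``labels`` is an
    optional tuple of row/column names (used for block matrices).
    """

    values: np.ndarray
    kind: str
    order_d: int | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"network matrix must be square, got {self.values.shape}")
        if self.kind not in NETWORK_KINDS:
            raise ValidationError(f"unknown network kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("network matrix contains non-finite entries")
        asym = np.max(np.abs(self.values - self.values.T), initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"network matrix asymmetric (max deviation {asym:.3g})")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    return ","


def read_timeseries(
    path: str | os.PathLike,
    delimiter: str | None = None,
    subject_id: str | None = None,
) -> RoiTimeSeries:
    """Read a delimited time-series table (rows = time, columns = regions).

    The delimiter is sniffed (tab vs comma) when not given. Non-rectangular
    tables raise a parse error; non-finite or missing cells raise a
    :class:`ValidationError` naming the offending row and column (1-based).
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    sid = subject_id if subject_id is not None else path.stem
    try:
        frame = pd.read_csv(
            path, sep=delim, header=None, comment="#", float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"non-rectangular table in {path}: {exc}") from exc
    if frame.empty:
        raise ValidationError(f"empty time-series file {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        t, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"missing or non-finite value in {path} at row {t + 1}, column {j + 1}"
        )
    return RoiTimeSeries(subject_id=sid, values=values)


def write_timeseries(
    ts: RoiTimeSeries, path: str | os.PathLike, delimiter: str = ","
) -> Path:
    """Write a time series as headerless delimited text. Returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.values, fmt="%.17g", delimiter=delimiter)
    return path


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest CSV with columns ``subject_id,label,path``.

    Labels may be given as +1/-1 integers or as the strings ``ASD``/``NC``
    (case-insensitive); they are mapped to +1 (patient) and -1 (control).
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"subject_id", "label", "path"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"manifest {path} missing column(s) {sorted(missing)}")
    if frame.empty:
        raise ValidationError("empty cohort")
    entries = []
    for _, row in frame.iterrows():
        raw = str(row["label"]).strip().lower()
        if raw not in LABEL_ALIASES:
            raise ValidationError(
                f"label {row['label']!r} for subject {row['subject_id']!r} is outside "
                f"the two-class vocabulary {sorted(LABEL_ALIASES)}"
            )
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = path.parent / p
        entries.append(
            ManifestEntry(
                subject_id=str(row["subject_id"]),
                label=LABEL_ALIASES[raw],
                path=p,
            )
        )
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in manifest.entries:
        p = e.path
        try:
            p = p.relative_to(path.parent)
        except ValueError:
            pass
        rows.append({"subject_id": e.subject_id, "label": e.label, "path": str(p)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_cohort(manifest: CohortManifest) -> list[RoiTimeSeries]:
    """Load every subject's time series listed in a manifest, in order."""
    return [read_timeseries(e.path, subject_id=e.subject_id) for e in manifest.entries]


def write_network(net: NetworkMatrix, path: str | os.PathLike, delimiter: str = ",") -> Path:
    """Write a network matrix with a one-line ``#`` metadata header.

    Round trip through :func:`read_network` reproduces values exactly
    (``%.17g`` formatting) and preserves ``kind`` and ``order_d``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"kind={net.kind} order_d={net.order_d if net.order_d is not None else 'none'} R={net.n_regions}"
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        np.savetxt(fh, net.values, fmt="%.17g", delimiter=delimiter)
    return path


def read_network(path: str | os.PathLike, delimiter: str = ",") -> NetworkMatrix:
    """Read a network matrix written by :func:`write_network`.

    Asymmetric matrices (beyond 1e-10) are rejected, as are kind/shape
    mismatches between the header and the data block.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValidationError(f"{path} has no '# kind=... order_d=... R=...' header")
        meta = dict(tok.split("=", 1) for tok in first[1:].split())
        body = fh.read()
    try:
        kind = meta["kind"]
        order_raw = meta["order_d"]
        n = int(meta["R"])
    except KeyError as exc:
        raise ValidationError(f"{path} header missing field {exc}") from exc
    order_d = None if order_raw == "none" else int(order_raw)
    values = np.loadtxt(io.StringIO(body), delimiter=delimiter)
    values = np.atleast_2d(values)
    if values.shape != (n, n):
        raise ValidationError(
            f"{path}: header declares R={n} but data block has shape {values.shape}"
        )
    return NetworkMatrix(values=values, kind=kind, order_d=order_d)


def default_region_labels(n_regions: int) -> list[str]:
    """Positional fallback names ``ROI_1 .. ROI_R`` (1-based, report style)."""
    return [f"ROI_{i + 1}" for i in range(n_regions)]


def read_region_labels(path: str | os.PathLike) -> list[str]:
    """Read an optional sidecar of region names, one per line."""
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not labels:
        raise ValidationError(f"empty region-label file {path}")
    return labels
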