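"""Synthetic ROI time-series cohorts with moment-level group differences.

The generator emulates the post-parcellation stage of a resting-state fMRI
study: per subject, an (M time points x R regions) matrix of region-averaged
BOLD-like signals. Regions are correlated Gaussian series whose pairwise
target correlation follows a slowly varying process — piecewise-constant over
blocks of roughly one sliding-window length — centred on a fixed base-coupling
matrix. The group effect lives in the *moments* of that modulation: on a
designated set of affected edges, the modulation's standard deviation (and
optionally its skewness) differs between the two groups, while the mean
coupling is identical. A pipeline that only looks at average FC therefore sees
nothing; one that summarises FC fluctuation (CM(d), Ho(d)) can recover the
effect.

Determinism: every subject draws from an independent RNG stream derived from
(master seed, group, subject index), so cohorts are bit-reproducible and
unchanged by generation order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from homnet.connectivity import SlidingWindowSpec, build_lodfcn
from homnet.data_io import (
    CohortManifest,
    ManifestEntry,
    RoiTimeSeries,
    ValidationError,
    write_manifest,
    write_timeseries,
)
from homnet.moment_features import build_cmfcn

logger = logging.getLogger(__name__)


def community_base_coupling(
    n_regions: int,
    n_communities: int = 4,
    within: float = 0.35,
    between: float = 0.05,
) -> np.ndarray:
    """Deterministic block-structured base coupling (brain-like communities).

    Regions are split into ``n_communities`` contiguous groups with stronger
    within-community than between-community coupling.
    """
    labels = np.arange(n_regions) * n_communities // n_regions
    base = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(base, 1.0)
    return base


def all_pairs(regions) -> tuple[tuple[int, int], ...]:
    """All unordered pairs among the given region indices."""
    regions = list(regions)
    return tuple(
        (regions[a], regions[b])
        for a in range(len(regions))
        for b in range(a + 1, len(regions))
    )


@dataclass
class SyntheticCohortSpec:
    """Conditions of a simulated two-group cohort.

    Defaults describe a moderate variance-level effect: 30 subjects per group,
    20 regions, a 170-time-point scan, coupling re-drawn every 30 time points
    (matching a W=30 sliding window), and the 10 edges among the first five
    regions modulated with standard deviation 0.3 in the patient group versus
    0.05 in controls. Unaffected edges share the background volatility in both
    groups. ``volatility`` and ``skew_shift`` map group label (+1 patient,
    -1 control) to the modulation scale / skew-normal shape on affected edges.
    """

    n_per_group: int = 30
    n_regions: int = 20
    n_timepoints: int = 170
    base_coupling: np.ndarray | None = None
    volatility: dict[int, float] = field(default_factory=lambda: {1: 0.3, -1: 0.05})
    skew_shift: dict[int, float] = field(default_factory=lambda: {1: 0.0, -1: 0.0})
    background_volatility: float = 0.05
    affected_edges: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: all_pairs(range(5))
    )
    block_length: int = 30
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need n_per_group >= 2")
        if self.n_regions < 2 or self.n_timepoints < 2:
            raise ValidationError("need at least 2 regions and 2 time points")
        if self.block_length < 1:
            raise ValidationError("block_length must be >= 1")
        if min(self.volatility.values(), default=0.0) < 0 or self.background_volatility < 0:
            raise ValidationError("volatility must be >= 0")
        if self.base_coupling is None:
            self.base_coupling = community_base_coupling(self.n_regions)
        self.base_coupling = np.asarray(self.base_coupling, dtype=float)
        if self.base_coupling.shape != (self.n_regions, self.n_regions):
            raise ValidationError("base_coupling shape must be (R, R)")
        if np.max(np.abs(self.base_coupling - self.base_coupling.T)) > 1e-10:
            raise ValidationError("base_coupling must be symmetric")
        if np.any(np.abs(self.base_coupling - np.diag(np.diag(self.base_coupling))) > 1):
            raise ValidationError("off-diagonal base couplings must lie in [-1, 1]")
        for i, j in self.affected_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValidationError(f"affected edge ({i}, {j}) out of range")

    def null(self) -> "SyntheticCohortSpec":
        """Copy with identical groups (no moment-level effect anywhere)."""
        v = self.background_volatility
        return SyntheticCohortSpec(
            n_per_group=self.n_per_group,
            n_regions=self.n_regions,
            n_timepoints=self.n_timepoints,
            base_coupling=self.base_coupling.copy(),
            volatility={1: v, -1: v},
            skew_shift={1: 0.0, -1: 0.0},
            background_volatility=v,
            affected_edges=self.affected_edges,
            block_length=self.block_length,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


def _standardized_skew_draw(rng, shape, a: float) -> np.ndarray:
    """Skew-normal draws standardized to mean 0, variance 1 (normal at a=0)."""
    if a == 0.0:
        return rng.standard_normal(shape)
    delta = a / np.sqrt(1.0 + a * a)
    mu = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - mu * mu)
    draws = stats.skewnorm.rvs(a, size=shape, random_state=rng)
    return (draws - mu) / sd


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a usable correlation matrix (PSD, unit diag)."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 1e-6, None)
    a = (v * w) @ v.T
    d = 1.0 / np.sqrt(np.diag(a))
    return a * np.outer(d, d)


def simulate_subject(
    spec: SyntheticCohortSpec, group: int, subject_index: int = 0
) -> RoiTimeSeries:
    """Simulate one subject's ROI time series.

    Coupling is re-drawn per block of ``block_length`` time points: target
    correlations are ``base_coupling + volatility * eps`` on affected edges
    (group-specific volatility and skew) and
    ``base_coupling + background_volatility * normal`` elsewhere, clipped into
    (-0.99, 0.99) with a warning when clipping occurs. Signals are correlated
    Gaussians per block with i.i.d. observation noise added.
    """
    if group not in (1, -1):
        raise ValidationError("group must be +1 or -1")
    r, m = spec.n_regions, spec.n_timepoints
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1 if group == 1 else 2, int(subject_index)])
    )
    affected = np.zeros((r, r), dtype=bool)
    for i, j in spec.affected_edges:
        affected[i, j] = affected[j, i] = True
    iu = np.triu_indices(r, k=1)
    vol_edge = np.where(affected[iu], spec.volatility[group], spec.background_volatility)
    skew = spec.skew_shift.get(group, 0.0)

    n_blocks = int(np.ceil(m / spec.block_length))
    out = np.empty((m, r))
    n_clipped = 0
    for b in range(n_blocks):
        eps = _standardized_skew_draw(rng, len(iu[0]), 0.0)
        if skew != 0.0:
            eps_skew = _standardized_skew_draw(rng, len(iu[0]), skew)
            eps = np.where(affected[iu], eps_skew, eps)
        target_upper = spec.base_coupling[iu] + vol_edge * eps
        clip = np.abs(target_upper) > 0.99
        n_clipped += int(clip.sum())
        target_upper = np.clip(target_upper, -0.99, 0.99)
        target = np.eye(r)
        target[iu] = target_upper
        target = target + np.triu(target, 1).T
        chol = np.linalg.cholesky(_nearest_correlation(target))
        lo = b * spec.block_length
        hi = min(m, lo + spec.block_length)
        out[lo:hi] = rng.standard_normal((hi - lo, r)) @ chol.T
    if n_clipped:
        warnings.warn(
            f"{n_clipped} requested correlation(s) outside (-0.99, 0.99) were clipped",
            stacklevel=2,
        )
    if spec.noise_sd > 0:
        out += spec.noise_sd * rng.standard_normal(out.shape)
    gtag = "pat" if group == 1 else "con"
    return RoiTimeSeries(subject_id=f"sub-{gtag}-{subject_index:03d}", values=out)


def simulate_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path | None = None
) -> tuple[list[RoiTimeSeries], CohortManifest]:
    """Simulate the full two-group cohort (patients first, then controls).

    When ``out_dir`` is given, per-subject CSVs and a ``manifest.csv`` are
    written there and the manifest's paths point at the files.
    """
    subjects: list[RoiTimeSeries] = []
    entries: list[ManifestEntry] = []
    for group in (1, -1):
        for idx in range(spec.n_per_group):
            ts = simulate_subject(spec, group, idx)
            subjects.append(ts)
            entries.append(
                ManifestEntry(
                    subject_id=ts.subject_id,
                    label=group,
                    path=Path(f"{ts.subject_id}.csv"),
                )
            )
    manifest = CohortManifest(entries=entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries2 = []
        for ts, e in zip(subjects, manifest.entries):
            p = write_timeseries(ts, out_dir / e.path)
            entries2.append(ManifestEntry(subject_id=e.subject_id, label=e.label, path=p))
        manifest = CohortManifest(entries=entries2)
        write_manifest(manifest, out_dir / "manifest.csv")
    logger.info(
        "simulated cohort: %d + %d subjects, R=%d, M=%d, %d affected edge(s)",
        spec.n_per_group, spec.n_per_group, spec.n_regions, spec.n_timepoints,
        len(spec.affected_edges),
    )
    return subjects, manifest


def edge_moment_group_stats(
    subjects: list[RoiTimeSeries],
    labels: np.ndarray,
    window: SlidingWindowSpec,
    order_d: int = 2,
) -> dict[str, np.ndarray]:
    """Realized per-edge group contrast of CM(d): t statistics and p-values.

    Measures, per edge, the two-sample t-test between groups of the subjects'
    CM(d) entries — the diagnostic the generator's injected effect should move
    on affected edges and not elsewhere. Returns R x R arrays ``t`` and ``p``.
    """
    labels = np.asarray(labels, dtype=int)
    cms = np.stack([build_cmfcn(build_lodfcn(ts, window), order_d).values for ts in subjects])
    a, b = cms[labels == 1], cms[labels == -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0)
    return {"t": np.asarray(res.statistic), "p": np.asarray(res.pvalue)}
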