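"""Classification pipeline: vectorize networks, select features, nested CV.

Per network type, each subject's symmetric R x R matrix is vectorized to its
strict lower triangle (R(R-1)/2 features, fixed column-major edge ordering).
Feature selection is a two-sample t-test filter followed by LASSO

    min_w  1/2 * sum_l (I_l - <y_l, w>)^2 + lambda * ||w||_1

(labels I_l in {+1, -1}); surviving features feed a linear soft-margin SVM.
Evaluation is repeated stratified 5-fold cross-validation; the filter
threshold, lambda and the SVM cost C are tuned on the training folds only, by
an inner (nested) 5-fold CV, so the outer test fold is touched exactly once.
All per-fold selections are logged, from which per-feature selection
frequencies over the repetitions x folds are computed.

Everything fit on a training fold — standardization statistics, t-test
p-values, the lambda grid anchor lambda_max = max |X^T y| — is computed from
that training fold alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from homnet.data_io import NetworkMatrix, ValidationError

COEF_TOL = 1e-8  # |w| above this counts as selected


def lower_triangle_index(n_regions: int) -> list[tuple[int, int]]:
    """Fixed edge ordering: strict lower triangle, column-major.

    Pairs (i, j) with i > j, ordered by column then row:
    (1,0), (2,0), ..., (R-1,0), (2,1), (3,1), ... 0-based; add 1 for reports.
    """
    jj, ii = np.triu_indices(n_regions, k=1)
    return list(zip(ii.tolist(), jj.tolist()))


def vectorize_lower(net: NetworkMatrix | np.ndarray) -> np.ndarray:
    """Vectorize a symmetric network's strict lower triangle.

    Uses the :func:`lower_triangle_index` ordering; length R(R-1)/2.
    """
    values = net.values if isinstance(net, NetworkMatrix) else np.asarray(net, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"expected a square matrix, got {values.shape}")
    if np.max(np.abs(values - values.T), initial=0.0) > 1e-10:
        raise ValidationError("cannot vectorize an asymmetric matrix")
    jj, ii = np.triu_indices(values.shape[0], k=1)
    return values[ii, jj].copy()


@dataclass
class FeatureTable:
    """Subjects x edge-features design matrix for one network type."""

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[tuple[int, int]]
    network_tag: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(
                f"X rows ({self.X.shape}) must align with labels ({self.y.shape})"
            )
        if self.X.shape[1] != len(self.feature_ids):
            raise ValidationError("feature_ids length must match X columns")
        if not set(np.unique(self.y)) <= {1, -1}:
            raise ValidationError("labels must be in {+1, -1}")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("non-finite feature values")


def build_feature_table(networks, labels, network_tag: str = "") -> FeatureTable:
    """Stack per-subject networks (same R, manifest order) into a FeatureTable."""
    mats = [n.values if hasattr(n, "values") else np.asarray(n) for n in networks]
    if not mats:
        raise ValidationError("no networks given")
    r = mats[0].shape[0]
    if any(m.shape != (r, r) for m in mats):
        raise ValidationError("all subjects must share the same region count")
    x = np.stack([vectorize_lower(m) for m in mats])
    return FeatureTable(
        X=x, y=np.asarray(labels, dtype=int),
        feature_ids=lower_triangle_index(r), network_tag=network_tag,
    )


def _ttest_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided two-sample t-test p-value per column (NaN where degenerate)."""
    a, b = x[y == 1], x[y == -1]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test needs >= 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0)
    return np.asarray(res.pvalue)


def ttest_filter(x: np.ndarray, y: np.ndarray, p_threshold: float) -> np.ndarray:
    """Boolean mask of features whose two-sample t-test p-value < threshold.

    Zero-variance features (undefined t) are excluded with a warning.
    """
    pvals = _ttest_pvalues(np.asarray(x, float), np.asarray(y, int))
    bad = ~np.isfinite(pvals)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance feature(s) excluded from t-test filter",
            stacklevel=2,
        )
    return np.isfinite(pvals) & (pvals < p_threshold)


def lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda with an all-zero LASSO solution: max |X^T y|."""
    return float(np.max(np.abs(x.T @ np.asarray(y, float)), initial=0.0))


def lasso_select(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """LASSO feature selection at penalty ``lam`` on the 1/2‖·‖² + λ‖·‖₁ scale.

    ``x`` should be column-standardized by the caller (penalties are
    scale-sensitive). Returns the boolean support mask |w| > 1e-8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite input to LASSO")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    return np.abs(_lasso_coef(x, y, lam)) > COEF_TOL


def _lasso_coef(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    # sklearn's Lasso minimises 1/(2n)‖y-Xw‖² + alpha‖w‖₁; alpha = lam/n maps
    # it onto the 1/2‖y-Xw‖² + lam‖w‖₁ objective (no intercept).
    n = x.shape[0]
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        return coef
    model = Lasso(alpha=lam / n, fit_intercept=False, max_iter=50_000, tol=1e-10)
    model.fit(x, y)
    return model.coef_


def train_svm(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> SVC:
    """Linear-kernel soft-margin SVM on the selected (standardized) features."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("SVM training needs both classes present")
    model = SVC(kernel="linear", C=c)
    model.fit(np.asarray(x, float), y)
    return model


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positives are the +1 (patient) class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, int)
        p = np.asarray(y_pred, int)
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == -1) & (p == -1))),
            fp=int(np.sum((t == -1) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == -1))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """ACC / TPR / TNR / F1 as percentages; NaN where a denominator is zero."""

    acc: float
    tpr: float
    tnr: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "TPR": self.tpr, "TNR": self.tnr, "F1": self.f1}


def classification_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity and F1 from confusion counts.

    ACC = (TP+TN)/(TP+FP+TN+FN), TPR = TP/(TP+FN), TNR = TN/(FP+TN),
    F1 = 2TP/(2TP+FN+FP), each as a percentage. A zero denominator yields NaN
    (undefined), with a warning.
    """

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    return Metrics(
        acc=ratio(c.tp + c.tn, c.total, "ACC"),
        tpr=ratio(c.tp, c.tp + c.fn, "TPR"),
        tnr=ratio(c.tn, c.fp + c.tn, "TNR"),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "F1"),
    )


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grids searched by the inner CV.

    ``lambda_fracs`` are fractions of the training fold's lambda_max (10-point
    log grid from 0.01 to 1 by default). Tie-breaks prefer larger lambda, then
    smaller C (more parsimonious models).
    """

    p_thresholds: tuple[float, ...] = (0.01, 0.05, 0.1)
    lambda_fracs: tuple[float, ...] = tuple(np.logspace(-2.0, 0.0, 10).tolist())
    svm_costs: tuple[float, ...] = (0.1, 1.0, 10.0)

    def candidates(self) -> list[tuple[float, float, float]]:
        """(p_threshold, lambda_frac, C) triples in tie-break preference order."""
        out = []
        for p in sorted(self.p_thresholds):
            for frac in sorted(self.lambda_fracs, reverse=True):
                for c in sorted(self.svm_costs):
                    out.append((p, frac, c))
        return out


@dataclass
class SelectionRecord:
    """Per-outer-fold log: feature mask and the tuned hyperparameters."""

    repetition: int
    fold: int
    mask: np.ndarray
    p_threshold: float
    lambda_frac: float
    lam: float
    svm_cost: float


@dataclass
class CvResult:
    """Outcome of repeated nested cross-validation for one network type."""

    network_tag: str
    y: np.ndarray
    repetitions: int
    seed: int
    fold_counts: list[ConfusionCounts]
    records: list[SelectionRecord]
    metrics: Metrics
    oof_predictions: np.ndarray  # (repetitions, L), entries in {+1, -1}
    fold_assignment: np.ndarray  # (repetitions, L), outer-fold id per subject
    mean_inner_accuracy: float


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0.0, sd, 1.0)
    return (x - mu) / sd, mu, sd


def _filter_mask(pvals: np.ndarray, p_threshold: float) -> np.ndarray:
    finite = np.isfinite(pvals)
    mask = finite & (pvals < p_threshold)
    if not mask.any():
        # degenerate filter: keep the single most discriminative feature so the
        # downstream stages always have input
        if not finite.any():
            raise ValidationError("all features have undefined t statistics")
        mask = np.zeros_like(mask)
        mask[np.nanargmin(np.where(finite, pvals, np.inf))] = True
    return mask


class _FoldModel:
    """Frozen fit of one (p_threshold, lambda_frac, C) on one training fold."""

    def __init__(self, x_tr, y_tr, p_threshold, lambda_frac, svm_cost, pvals=None):
        if pvals is None:
            pvals = _ttest_pvalues(x_tr, y_tr)
        self.t_mask = _filter_mask(pvals, p_threshold)
        xs, self.mu, self.sd = _standardize_fit(x_tr[:, self.t_mask])
        self.lam = lambda_frac * lambda_max(xs, y_tr)
        local = np.abs(_lasso_coef(xs, y_tr.astype(float), self.lam)) > COEF_TOL
        if not local.any():
            local = np.ones(xs.shape[1], dtype=bool)  # lasso killed everything: fall back to t-test set
        self.lasso_mask = local
        self.mask = np.zeros_like(self.t_mask)
        self.mask[np.flatnonzero(self.t_mask)[local]] = True
        self.model = train_svm(xs[:, local], y_tr, svm_cost)
        self.p_threshold, self.lambda_frac, self.svm_cost = p_threshold, lambda_frac, svm_cost

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (x[:, self.t_mask] - self.mu) / self.sd
        return self.model.predict(xs[:, self.lasso_mask])


def _inner_search(x_tr, y_tr, grid: HyperGrid, inner_seed: int):
    """Pick (p_threshold, lambda_frac, C) by mean inner 5-fold accuracy."""
    cands = grid.candidates()
    correct = np.zeros(len(cands))
    total = np.zeros(len(cands))
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=inner_seed)
    for itr, ival in skf.split(x_tr, y_tr):
        xi, yi = x_tr[itr], y_tr[itr]
        xv, yv = x_tr[ival], y_tr[ival]
        pvals = _ttest_pvalues(xi, yi)
        idx = 0
        for p in sorted(grid.p_thresholds):
            t_mask = _filter_mask(pvals, p)
            xs, mu, sd = _standardize_fit(xi[:, t_mask])
            xvs = (xv[:, t_mask] - mu) / sd
            lmax = lambda_max(xs, yi)
            for frac in sorted(grid.lambda_fracs, reverse=True):
                local = np.abs(_lasso_coef(xs, yi.astype(float), frac * lmax)) > COEF_TOL
                if not local.any():
                    local = np.ones(xs.shape[1], dtype=bool)
                for c in sorted(grid.svm_costs):
                    model = train_svm(xs[:, local], yi, c)
                    pred = model.predict(xvs[:, local])
                    correct[idx] += np.sum(pred == yv)
                    total[idx] += len(yv)
                    idx += 1
    acc = correct / np.maximum(total, 1)
    best = int(np.argmax(acc))  # argmax keeps the first (preferred) on ties
    return cands[best], float(acc[best])


def fit_fold(
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    grid: HyperGrid,
    inner_seed: int,
    repetition: int = 0,
    fold: int = 0,
) -> tuple[SelectionRecord, np.ndarray, float]:
    """Tune on the training fold, fit once, predict the test fold.

    Only ``x[train_idx], y[train_idx]`` influence tuning, selection and the
    fitted model; the test fold enters solely through the final prediction.
    Returns (selection record, test predictions, mean inner accuracy).
    """
    x_tr, y_tr = x[train_idx], y[train_idx]
    (p, frac, c), inner_acc = _inner_search(x_tr, y_tr, grid, inner_seed)
    fm = _FoldModel(x_tr, y_tr, p, frac, c)
    record = SelectionRecord(
        repetition=repetition, fold=fold, mask=fm.mask,
        p_threshold=p, lambda_frac=frac, lam=fm.lam, svm_cost=c,
    )
    return record, fm.predict(x[test_idx]), inner_acc


def aggregate_metrics(fold_counts: list[ConfusionCounts]) -> Metrics:
    """Mean over folds of the per-fold metrics (NaN-aware)."""
    per = [classification_metrics(c) for c in fold_counts]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return Metrics(
            acc=float(np.nanmean([m.acc for m in per])),
            tpr=float(np.nanmean([m.tpr for m in per])),
            tnr=float(np.nanmean([m.tnr for m in per])),
            f1=float(np.nanmean([m.f1 for m in per])),
        )


def nested_cv(
    table: FeatureTable,
    repetitions: int = 10,
    seed: int = 0,
    grid: HyperGrid | None = None,
    n_outer_folds: int = 5,
) -> CvResult:
    """Repeated stratified 5-fold CV with nested hyperparameter tuning.

    Each repetition draws a fresh stratified partition (seeded from the master
    seed, so the whole procedure is reproducible bit-for-bit); every subject
    is predicted exactly once per repetition. Aggregate metrics are the mean
    over all outer folds of all repetitions.
    """
    grid = grid or HyperGrid()
    x, y = table.X, table.y
    n = len(y)
    if n < 10:
        raise ValidationError(f"nested CV needs >= 10 subjects, got {n}")
    if len(np.unique(y)) < 2:
        raise ValidationError("nested CV needs both classes present")
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * repetitions * n_outer_folds + repetitions).astype(np.int64)
    outer_seeds = states[:repetitions] % (2**31)
    inner_seeds = states[repetitions:].reshape(2, repetitions, n_outer_folds)[0] % (2**31)

    records: list[SelectionRecord] = []
    fold_counts: list[ConfusionCounts] = []
    oof = np.zeros((repetitions, n), dtype=int)
    assignment = np.full((repetitions, n), -1, dtype=int)
    inner_accs: list[float] = []
    for rep in range(repetitions):
        skf = StratifiedKFold(
            n_splits=n_outer_folds, shuffle=True, random_state=int(outer_seeds[rep])
        )
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            record, pred, inner_acc = fit_fold(
                x, y, tr, te, grid,
                inner_seed=int(inner_seeds[rep, fold]),
                repetition=rep, fold=fold,
            )
            records.append(record)
            fold_counts.append(ConfusionCounts.from_predictions(y[te], pred))
            oof[rep, te] = pred
            assignment[rep, te] = fold
            inner_accs.append(inner_acc)
    return CvResult(
        network_tag=table.network_tag,
        y=y.copy(),
        repetitions=repetitions,
        seed=seed,
        fold_counts=fold_counts,
        records=records,
        metrics=aggregate_metrics(fold_counts),
        oof_predictions=oof,
        fold_assignment=assignment,
        mean_inner_accuracy=float(np.mean(inner_accs)),
    )


def selection_frequency(records: list[SelectionRecord]) -> np.ndarray:
    """Fraction of folds in which each feature survived selection.

    With 10 repetitions of 5-fold CV the denominator is 50; a feature kept in
    49 of those folds has frequency 0.98.
    """
    if not records:
        raise ValidationError("no selection records")
    dims = {len(r.mask) for r in records}
    if len(dims) != 1:
        raise ValidationError(f"inconsistent feature dimensions across records: {sorted(dims)}")
    return np.mean([r.mask for r in records], axis=0)
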