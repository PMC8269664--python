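"""Majority-voting combination of per-network classifiers.

Each network type (C-FCN, RMS, CM(d), Ho(d)) yields its own cross-validated
classifier. A voting strategy combines T of them: a label is assigned when it
receives more than T/2 votes, otherwise the vote is formally rejected. With
odd T and binary labels a strict majority always exists, so rejection can only
occur for even panels; a rejected subject falls back to the vote of a
designated member (by default the member with the best inner-CV accuracy).

Combining cross-validated learners requires their out-of-fold predictions to
be aligned: every member must have been evaluated under identical fold
partitions (same master seed), which is checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from homnet.data_io import ValidationError
from homnet.ml_pipeline import (
    ConfusionCounts,
    CvResult,
    Metrics,
    aggregate_metrics,
)


@dataclass
class VotePanel:
    """Votes of T learners on L subjects; entries in {+1, -1}."""

    learner_tags: list[str]
    predictions: np.ndarray  # (T, L)

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=int)
        if self.predictions.ndim != 2:
            raise ValidationError("predictions must be a (T, L) matrix")
        if self.predictions.shape[0] != len(self.learner_tags):
            raise ValidationError("one tag per learner row required")
        if self.predictions.shape[0] < 1:
            raise ValidationError("empty vote panel")
        if not set(np.unique(self.predictions)) <= {1, -1}:
            raise ValidationError("votes must be in {+1, -1}")

    @property
    def n_learners(self) -> int:
        return self.predictions.shape[0]


def majority_vote(
    panel: VotePanel, fallback_learner: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Combine votes: a label wins when it gets more than T/2 of T votes.

    Returns ``(labels, rejected)``. ``rejected`` marks subjects where no label
    reached a strict majority (possible only for even T); those subjects are
    resolved to the fallback learner's vote. Permuting learner order never
    changes the outcome.
    """
    t = panel.n_learners
    plus = np.sum(panel.predictions == 1, axis=0)
    minus = t - plus
    labels = np.where(plus > t / 2, 1, np.where(minus > t / 2, -1, 0))
    rejected = labels == 0
    if rejected.any():
        if not (0 <= fallback_learner < t):
            raise ValidationError(f"fallback learner index {fallback_learner} out of range")
        labels = np.where(rejected, panel.predictions[fallback_learner], labels)
    return labels.astype(int), rejected


@dataclass
class StrategyResult:
    """Metrics of one voting strategy, plus bookkeeping."""

    member_tags: list[str]
    metrics: Metrics
    fold_counts: list[ConfusionCounts]
    combined_predictions: np.ndarray  # (repetitions, L)
    n_rejections: int


def evaluate_strategy(
    member_tags: list[str],
    cv_results: dict[str, CvResult],
    fallback: str = "best_inner",
) -> StrategyResult:
    """Evaluate a voting strategy over aligned out-of-fold predictions.

    For every repetition, each member's out-of-fold predictions are combined
    per subject by majority vote; metrics are then aggregated exactly as a
    single learner's (mean over the outer folds of all repetitions), so a
    one-member strategy reproduces that member's CvResult metrics.

    ``fallback`` resolves rejected (tied) votes: ``"best_inner"`` uses the
    member with the highest mean inner-CV accuracy, or pass a member tag.
    """
    if not member_tags:
        raise ValidationError("empty voting strategy")
    missing = [t for t in member_tags if t not in cv_results]
    if missing:
        raise ValidationError(f"no CV result for member(s) {missing}")
    members = [cv_results[t] for t in member_tags]
    ref = members[0]
    for m in members[1:]:
        if not np.array_equal(m.fold_assignment, ref.fold_assignment):
            raise ValidationError(
                "members were evaluated under different fold partitions; "
                "voting requires aligned out-of-fold predictions (same master seed)"
            )
        if not np.array_equal(m.y, ref.y):
            raise ValidationError("members disagree on subject labels/order")
    if fallback == "best_inner":
        fb = int(np.argmax([m.mean_inner_accuracy for m in members]))
    else:
        if fallback not in member_tags:
            raise ValidationError(f"fallback tag {fallback!r} not in strategy")
        fb = member_tags.index(fallback)

    reps, n = ref.oof_predictions.shape
    combined = np.zeros((reps, n), dtype=int)
    n_rejections = 0
    fold_counts: list[ConfusionCounts] = []
    for rep in range(reps):
        panel = VotePanel(
            learner_tags=list(member_tags),
            predictions=np.stack([m.oof_predictions[rep] for m in members]),
        )
        labels, rejected = majority_vote(panel, fallback_learner=fb)
        combined[rep] = labels
        n_rejections += int(rejected.sum())
        for fold in np.unique(ref.fold_assignment[rep]):
            sel = ref.fold_assignment[rep] == fold
            fold_counts.append(
                ConfusionCounts.from_predictions(ref.y[sel], labels[sel])
            )
    return StrategyResult(
        member_tags=list(member_tags),
        metrics=aggregate_metrics(fold_counts),
        fold_counts=fold_counts,
        combined_predictions=combined,
        n_rejections=n_rejections,
    )
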