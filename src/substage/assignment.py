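"""Per-subject subtyping and staging from the posterior over models.

Subjects are assigned by averaging their subtype x stage likelihood over
the MCMC samples (so model uncertainty propagates into the assignment),
taking the most probable subtype, and then the most probable stage under
that subtype.  The *strength of assignment* separates early subjects — who
plausibly sit at stage <= 2 of any subtype and carry no subtype signal —
from subjects confidently placed at stage 3 or later of one subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import (
    BiomarkerDataset,
    LikelihoodEngine,
    NoiseModel,
    ZScoreEventSet,
)
from .mcmc import MCMCSamples

__all__ = [
    "SubjectAssignment",
    "assign_subjects",
    "strength_of_assignment",
    "threshold_classify",
    "optimise_thresholds",
    "cross_validated_threshold_accuracy",
]


@dataclass
class SubjectAssignment:
    """Subtype and stage posterior summary for one subject."""

    subject_id: str
    subtype_probabilities: np.ndarray   # (C,), stage-marginalised
    ml_subtype: int
    stage_probabilities: np.ndarray     # (N+1,), under ml_subtype
    ml_stage: int
    expected_stage: float
    strength: float | None = None
    strongly_assigned: bool | None = None
    valid: bool = True


def _joint_posterior(data: BiomarkerDataset, samples: MCMCSamples,
                     event_set: ZScoreEventSet, noise: NoiseModel,
                     quadrature_points: int = 10, max_samples: int = 1000,
                     ) -> np.ndarray:
    """(J, C, N+1) posterior over subtype and stage, MCMC-averaged.

    Per sample the joint likelihood f_c x (stage integral) is accumulated
    in linear space after a per-subject shift, then normalised per subject.
    """
    eng = LikelihoodEngine(data, event_set, noise, quadrature_points)
    C, N = samples.n_subtypes, samples.n_events
    idx = np.arange(samples.n_samples)
    if samples.n_samples > max_samples:
        idx = np.linspace(0, samples.n_samples - 1, max_samples).astype(int)
    J = data.n_subjects
    acc = np.zeros((J, C, N + 1))
    shift = None
    cur = np.empty((J, C, N + 1))
    for s in idx:
        with np.errstate(divide="ignore"):
            logf = np.log(samples.fractions[s])
        for c in range(C):
            cur[:, c] = eng.stage_log_likelihood(
                samples.sequences[s, c].astype(int)) + logf[c]
        if shift is None:
            # per-subject shift from the first sample, reused throughout;
            # it cancels in the final normalisation
            shift = cur.max(axis=(1, 2))
        acc += np.exp(cur - shift[:, None, None])
    acc /= len(idx)
    totals = acc.sum(axis=(1, 2))
    valid = totals > 0
    out = np.full_like(acc, np.nan)
    out[valid] = acc[valid] / totals[valid, None, None]
    return out


def assign_subjects(data: BiomarkerDataset, samples: MCMCSamples,
                    event_set: ZScoreEventSet, noise: NoiseModel,
                    quadrature_points: int = 10, max_samples: int = 1000,
                    ) -> list[SubjectAssignment]:
    """Subtype and stage each subject, integrating over MCMC samples.

    ``max_samples`` evenly thins the chain before averaging, which bounds
    the cost without biasing the posterior summary.  Subjects with all
    biomarkers missing are returned flagged invalid.
    """
    if samples.n_samples == 0:
        raise ValueError("empty MCMC sample set")
    joint = _joint_posterior(data, samples, event_set, noise,
                             quadrature_points, max_samples)
    n_events = samples.n_events
    all_missing = ~np.isfinite(data.values).any(axis=1)
    out = []
    for j in range(data.n_subjects):
        if all_missing[j]:
            C = samples.n_subtypes
            out.append(SubjectAssignment(
                data.subject_ids[j], np.full(C, np.nan), -1,
                np.full(n_events + 1, np.nan), -1, np.nan, valid=False))
            continue
        jt = joint[j]
        subtype_p = jt.sum(axis=1)
        ml_subtype = int(np.argmax(subtype_p))
        stage_p = jt[ml_subtype] / jt[ml_subtype].sum()
        ml_stage = int(np.argmax(stage_p))
        expected = float(np.dot(stage_p, np.arange(n_events + 1)))
        a = SubjectAssignment(data.subject_ids[j], subtype_p, ml_subtype,
                              stage_p, ml_stage, expected)
        if n_events >= 3:
            a.strength, a.strongly_assigned = strength_of_assignment(jt)
        out.append(a)
    return out


def strength_of_assignment(joint: np.ndarray) -> tuple[float, bool]:
    """Strength rule on a normalised subtype x stage posterior (C, N+1).

    The probability of being at stage <= 2 is pooled across subtypes (at
    those stages there is no meaningful subtype signal); each subtype's
    probability is summed over stages 3 and later, and the strength is the
    largest of these.  The assignment is strong only when the strength is
    strictly greater than one half.
    """
    joint = np.asarray(joint, float)
    if joint.ndim != 2 or joint.shape[1] < 4:
        raise ValueError(
            "strength-of-assignment rule needs stages 3+ (at least 3 events)")
    late = joint[:, 3:].sum(axis=1)
    strength = float(late.max())
    return strength, strength > 0.5


# ---------------------------------------------------------------------------
# Threshold-based classification harness
# ---------------------------------------------------------------------------

def threshold_classify(subtype_probs: np.ndarray, thresholds: np.ndarray,
                       labels: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Classify subjects by thresholded subtype probability.

    A subject is assigned to the highest-probability subtype whose
    probability exceeds its threshold; subjects clearing no threshold stay
    unassigned (column C of the confusion table) and count as errors.
    Returns (confusion table [class x C+1], per-class accuracy, balanced
    accuracy).  ``labels`` are integer class indices aligned with subtypes.
    """
    subtype_probs = np.asarray(subtype_probs, float)
    thresholds = np.asarray(thresholds, float)
    labels = np.asarray(labels)
    if labels.shape[0] != subtype_probs.shape[0]:
        raise ValueError("one label per subject required")
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    C = subtype_probs.shape[1]
    qualifies = subtype_probs > thresholds[None, :]
    masked = np.where(qualifies, subtype_probs, -np.inf)
    pred = np.where(qualifies.any(axis=1), np.argmax(masked, axis=1), C)
    n_classes = int(labels.max()) + 1
    confusion = np.zeros((n_classes, C + 1), dtype=int)
    for true, p in zip(labels, pred):
        confusion[int(true), int(p)] += 1
    per_class = np.array([
        confusion[k, k] / confusion[k].sum() if confusion[k].sum() else np.nan
        for k in range(n_classes)])
    balanced = float(np.nanmean(per_class))
    return confusion, per_class, balanced


def optimise_thresholds(subtype_probs: np.ndarray, labels: np.ndarray,
                        grid_step: float = 0.05) -> tuple[np.ndarray, float]:
    """Grid search per-subtype thresholds maximising balanced accuracy."""
    C = subtype_probs.shape[1]
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    best_thr, best_acc = np.zeros(C), -np.inf
    for combo in product(grid, repeat=C):
        thr = np.asarray(combo)
        _, _, acc = threshold_classify(subtype_probs, thr, labels)
        if acc > best_acc:
            best_thr, best_acc = thr, acc
    return best_thr, float(best_acc)


def cross_validated_threshold_accuracy(subtype_probs: np.ndarray,
                                       labels: np.ndarray, n_folds: int = 10,
                                       seed: int | None = None,
                                       grid_step: float = 0.05) -> float:
    """Out-of-sample balanced accuracy of threshold-optimised assignment.

    Thresholds are tuned on each training fold and applied to the held-out
    fold; the pooled held-out predictions give the reported accuracy.
    """
    from .selection import make_folds

    labels = np.asarray(labels)
    folds = make_folds(len(labels), n_folds, seed, stratify_by=labels)
    pred_probs, pred_labels, pred_thr = [], [], []
    for train, test in folds:
        thr, _ = optimise_thresholds(subtype_probs[train], labels[train],
                                     grid_step)
        pred_probs.append(subtype_probs[test])
        pred_labels.append(labels[test])
        pred_thr.append((thr, len(test)))
    # score each held-out block with its fold's thresholds, then pool
    accs, weights = [], []
    for (thr, n), probs, lab in zip(pred_thr, pred_probs, pred_labels):
        _, _, acc = threshold_classify(probs, thr, lab)
        accs.append(acc)
        weights.append(n)
    return float(np.average(accs, weights=weights))
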