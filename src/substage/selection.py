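"""Model selection: cross-validated likelihood, CVIC, and pattern similarity.

The number of subtypes is chosen with the cross-validation information
criterion, CVIC = -2 x (summed out-of-sample log-likelihood): each fold's
models are fitted on the training subjects and scored on the held-out
subjects.  Following the usual parsimony convention, the smallest model
whose CVIC lies within 6 of the minimum is selected.  Consistency of the
progression patterns across folds is summarised by the cross-validation
similarity (CVS): the Bhattacharyya overlap between event-position
distributions of fold models and the full-data model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BiomarkerDataset,
    NoiseModel,
    ZScoreEventSet,
    mixture_log_likelihood,
)
from .fitting import FitResult, fit_hierarchical
from .mcmc import PositionalDistribution

__all__ = [
    "CVResult",
    "make_folds",
    "cross_validate",
    "select_n_subtypes",
    "bhattacharyya_event_similarity",
    "cross_validation_similarity",
]


@dataclass
class CVResult:
    """Cross-validation outcome: folds, fold models, CVIC, selection."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    fold_models: list[list[FitResult]]       # [fold][C-1]
    test_log_likelihoods: np.ndarray         # (n_folds, c_max)
    cvic: np.ndarray                         # (c_max,)
    selected_c: int
    cvs: np.ndarray | None = None            # per subtype of the full model
    meta: dict = field(default_factory=dict)


def make_folds(n_subjects: int, n_folds: int, seed: int | None = None,
               stratify_by: np.ndarray | None = None,
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (optionally stratified) partition into train/test index pairs."""
    from sklearn.model_selection import KFold, StratifiedKFold

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_subjects < n_folds:
        raise ValueError("need at least one subject per fold")
    X = np.zeros((n_subjects, 1))
    if stratify_by is not None:
        splitter = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, np.asarray(stratify_by))
    else:
        splitter = KFold(n_folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    return [(tr.copy(), te.copy()) for tr, te in split]


def cross_validate(data: BiomarkerDataset, event_set: ZScoreEventSet,
                   noise: NoiseModel | None = None, c_max: int = 3,
                   n_folds: int = 10, seed: int | None = None,
                   stratify_by: np.ndarray | None = None,
                   n_restarts: int = 25, quadrature_points: int = 10,
                   em_tol: float = 1e-6, em_max_iter: int = 100) -> CVResult:
    """Ten-fold (by default) cross-validation of the subtype count.

    For every fold the full hierarchy C = 1..c_max is refitted on the
    training subjects and each model's mixture log-likelihood is evaluated
    on the held-out subjects; CVIC aggregates across folds.
    """
    noise = noise or NoiseModel.unit(event_set.n_biomarkers)
    folds = make_folds(data.n_subjects, n_folds, seed, stratify_by)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(n_folds)]
    test_ll = np.full((n_folds, c_max), np.nan)
    fold_models: list[list[FitResult]] = []
    for f, (train, test) in enumerate(folds):
        if len(test) == 0:
            raise ValueError("fold with zero test subjects")
        fits = fit_hierarchical(data.subset(train), event_set, noise, c_max,
                                n_restarts, fold_seeds[f], quadrature_points,
                                em_tol, em_max_iter)
        fold_models.append(fits)
        test_data = data.subset(test)
        for ci, fit in enumerate(fits):
            ll, _ = mixture_log_likelihood(test_data, fit.model,
                                           quadrature_points)
            test_ll[f, ci] = ll
    # a fold hierarchy may have stopped early; drop C values missing anywhere
    valid = ~np.isnan(test_ll).any(axis=0)
    c_valid = int(valid.sum())
    if c_valid < c_max:
        warnings.warn(f"hierarchies truncated; CVIC computed for C=1..{c_valid}")
    cvic = -2.0 * test_ll[:, :c_valid].sum(axis=0)
    selected = select_n_subtypes(cvic)
    return CVResult(folds, fold_models, test_ll[:, :c_valid], cvic, selected,
                    meta={"n_folds": n_folds, "seed": seed,
                          "n_restarts": n_restarts})


def select_n_subtypes(cvic: np.ndarray) -> int:
    """Smallest subtype count whose CVIC is within 6 of the minimum.

    A CVIC difference below 6 (3 in log-likelihood) is treated as weak
    evidence for the more complex model, so parsimony wins.
    """
    cvic = np.asarray(cvic, dtype=float)
    if cvic.size == 0:
        raise ValueError("empty CVIC list")
    within = np.flatnonzero(cvic - cvic.min() < 6.0)
    return int(within[0]) + 1


def bhattacharyya_event_similarity(pos_a: np.ndarray, pos_b: np.ndarray) -> float:
    """Mean Bhattacharyya coefficient between two event-position matrices.

    Both arguments are N x N matrices whose row e is the distribution of
    event e's position for one subtype; per event the coefficient is
    sum_p sqrt(p_a p_b), and the mean over events is returned.  It is 1 for
    identical distributions and 0 for disjoint ones.
    """
    pos_a = np.asarray(pos_a, float)
    pos_b = np.asarray(pos_b, float)
    if pos_a.shape != pos_b.shape or pos_a.ndim != 2:
        raise ValueError("positional matrices must have identical N x N shape")
    return float(np.sqrt(pos_a * pos_b).sum(axis=1).mean())


def cross_validation_similarity(full_pos: PositionalDistribution,
                                fold_pos: list[PositionalDistribution],
                                ) -> np.ndarray:
    """CVS: per full-model subtype, mean similarity to its matched fold subtype.

    For each fold, subtypes are paired greedily by highest Bhattacharyya
    similarity; full-model subtypes left unmatched in a fold (fold model
    with fewer subtypes) are excluded from that fold's mean with a warning.
    """
    C = full_pos.n_subtypes
    sims = np.full((len(fold_pos), C), np.nan)
    for f, fp in enumerate(fold_pos):
        pairs = _greedy_match(full_pos, fp)
        for c_full, c_fold in pairs:
            sims[f, c_full] = bhattacharyya_event_similarity(
                full_pos.subtype(c_full), fp.subtype(c_fold))
        if fp.n_subtypes < C:
            warnings.warn(
                f"fold {f} model has {fp.n_subtypes} subtypes < {C}; "
                "unmatched subtypes excluded from CVS")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sims, axis=0)


def _greedy_match(pos_a: PositionalDistribution, pos_b: PositionalDistribution,
                  ) -> list[tuple[int, int]]:
    """Greedy maximum-similarity bipartite pairing of subtypes."""
    sim = np.array([[bhattacharyya_event_similarity(pos_a.subtype(i),
                                                    pos_b.subtype(j))
                     for j in range(pos_b.n_subtypes)]
                    for i in range(pos_a.n_subtypes)])
    pairs = []
    sim = sim.copy()
    for _ in range(min(sim.shape)):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        pairs.append((int(i), int(j)))
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return pairs
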