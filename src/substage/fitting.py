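"""Maximum-likelihood fitting of subtype sequences and mixture fractions.

The sequence space is discrete, so fitting alternates greedy coordinate
ascent over event positions with expectation-maximisation updates of the
mixture fractions.  Models with more subtypes are fitted hierarchically:
each C-subtype model is initialised by splitting one cluster of the best
(C-1)-subtype model, and the best of the candidate splits is kept.  Every
greedy search is restarted from multiple random admissible sequences to
guard against local optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    BiomarkerDataset,
    LikelihoodEngine,
    NoiseModel,
    SubtypeMixtureModel,
    SubtypeSequence,
    ZScoreEventSet,
    mixture_log_likelihood,
    random_admissible_sequence,
)

__all__ = [
    "FitResult",
    "optimise_sequence_greedy",
    "fit_single_cluster",
    "split_cluster_em",
    "fit_hierarchical",
    "update_fractions",
]


@dataclass
class FitResult:
    """Outcome of one model fit."""

    model: SubtypeMixtureModel
    log_likelihood: float
    restart_log_likelihoods: list[float] = field(default_factory=list)
    seed: int | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_subtypes(self) -> int:
        return self.model.n_subtypes


# ---------------------------------------------------------------------------
# Greedy coordinate ascent over event positions
# ---------------------------------------------------------------------------

def _candidate_orders(order: np.ndarray, event: int,
                      event_set: ZScoreEventSet) -> np.ndarray:
    """All admissible re-insertions of ``event`` with the rest held fixed.

    The candidate list always includes the current placement.
    """
    base = order[order != event]
    bm = event_set.event_biomarker[event]
    siblings = event_set.biomarker_events(bm)
    r = int(np.flatnonzero(siblings == event)[0])
    lo = 0 if r == 0 else int(np.flatnonzero(base == siblings[r - 1])[0]) + 1
    hi = len(base) if r == len(siblings) - 1 else int(
        np.flatnonzero(base == siblings[r + 1])[0])
    return np.stack([np.insert(base, p, event) for p in range(lo, hi + 1)])


def _subject_ll_batch(engine: LikelihoodEngine, orders: np.ndarray) -> np.ndarray:
    """(B, J) per-subject log P(x_j | S) for a batch of orderings."""
    return engine.subject_log_likelihood_batch(orders)


def _greedy(engine: LikelihoodEngine, order: np.ndarray,
            other_log: np.ndarray | None = None, log_frac: float = 0.0,
            max_passes: int | None = None,
            ) -> tuple[np.ndarray, float, list[float]]:
    """Greedy repositioning of each event in turn until a full pass is stable.

    With ``other_log`` given (per-subject log of the other mixture
    components' contribution, including their fractions), the objective is
    the full mixture log-likelihood; otherwise the single-sequence one.
    Exact ties keep the current position.
    """
    def objective(sll: np.ndarray) -> np.ndarray:
        if other_log is None:
            return sll.sum(axis=1)
        return np.logaddexp(other_log[None, :], log_frac + sll).sum(axis=1)

    cur = np.asarray(order).copy()
    cur_ll = float(objective(_subject_ll_batch(engine, cur[None, :]))[0])
    trace = [cur_ll]
    n = engine.n_events
    changed = True
    passes = 0
    while changed and (max_passes is None or passes < max_passes):
        changed = False
        passes += 1
        for event in range(n):
            cands = _candidate_orders(cur, event, engine.event_set)
            if len(cands) == 1:
                continue
            lls = objective(_subject_ll_batch(engine, cands))
            best = int(np.argmax(lls))
            if lls[best] > cur_ll and not np.array_equal(cands[best], cur):
                cur = cands[best]
                cur_ll = float(lls[best])
                changed = True
        trace.append(cur_ll)
    return cur, cur_ll, trace


def optimise_sequence_greedy(data: BiomarkerDataset, initial: SubtypeSequence,
                             event_set: ZScoreEventSet, noise: NoiseModel,
                             quadrature_points: int = 10) -> SubtypeSequence:
    """Greedy single-sequence optimisation from a given starting sequence.

    Each event in turn is moved to its likelihood-maximising admissible
    position with the relative order of all other events fixed; passes
    repeat until no event moves.  The result's likelihood is never below
    the starting likelihood.
    """
    eng = LikelihoodEngine(data, event_set, noise, quadrature_points)
    order, _, _ = _greedy(eng, initial.order)
    return SubtypeSequence(order)


# ---------------------------------------------------------------------------
# Single-cluster fitting
# ---------------------------------------------------------------------------

def fit_single_cluster(data: BiomarkerDataset, event_set: ZScoreEventSet,
                       noise: NoiseModel | None = None, n_restarts: int = 25,
                       seed: int | None = None, quadrature_points: int = 10,
                       ) -> FitResult:
    """Maximum-likelihood single sequence from multiple random restarts."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    noise = noise or NoiseModel.unit(event_set.n_biomarkers)
    eng = LikelihoodEngine(data, event_set, noise, quadrature_points)
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best_order, best_ll, best_trace = None, -np.inf, []
    restart_lls = []
    for ss in children:
        rng = np.random.default_rng(ss)
        start = random_admissible_sequence(event_set, rng)
        order, ll, trace = _greedy(eng, start.order)
        restart_lls.append(ll)
        if ll > best_ll:
            best_order, best_ll, best_trace = order, ll, trace
    model = SubtypeMixtureModel(event_set, [SubtypeSequence(best_order)],
                                np.array([1.0]), noise)
    return FitResult(model, best_ll, restart_lls, seed,
                     list(enumerate(best_trace)),
                     meta={"n_restarts": n_restarts,
                           "quadrature_points": quadrature_points})


# ---------------------------------------------------------------------------
# Mixture E-M
# ---------------------------------------------------------------------------

def _mixture_ll(sll: np.ndarray, fractions: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        logf = np.log(fractions)
    return float(logsumexp(logf[:, None] + sll, axis=0).sum())


def _responsibilities(sll: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logf = np.log(fractions)
    joint = logf[:, None] + sll              # (C, J)
    return np.exp(joint - logsumexp(joint, axis=0)[None, :])


def _em_refine(engine: LikelihoodEngine, orders: list[np.ndarray],
               fractions: np.ndarray, tol: float = 1e-6, max_iter: int = 100,
               ) -> tuple[list[np.ndarray], np.ndarray, float, list[float]]:
    """Alternate greedy sequence updates and fraction E-M steps.

    Sequence updates maximise the full mixture likelihood directly
    (coordinate ascent), so the trace is monotone up to the E-M tolerance.
    """
    C = len(orders)
    orders = [np.asarray(o).copy() for o in orders]
    fractions = np.asarray(fractions, float).copy()
    sll = np.stack([_subject_ll_batch(engine, o[None, :])[0] for o in orders])
    ll = _mixture_ll(sll, fractions)
    trace = [ll]
    for _ in range(max_iter):
        # fraction E-M steps are engine-free, so run them to convergence
        # before paying for another sequence pass
        for _ in range(max_iter):
            fractions = _responsibilities(sll, fractions).mean(axis=1)
            fractions = fractions / fractions.sum()
            new_ll = _mixture_ll(sll, fractions)
            if new_ll - ll < tol:
                ll = max(ll, new_ll)
                break
            ll = new_ll
        with np.errstate(divide="ignore"):
            logf = np.log(fractions)
        changed = False
        for c in range(C):
            mask = np.ones(C, bool)
            mask[c] = False
            if C > 1:
                other = logsumexp(logf[mask, None] + sll[mask], axis=0)
            else:
                other = np.full(engine.n_subjects, -np.inf)
            # one greedy pass per outer iteration: coordinate ascent stays
            # monotone and the outer loop handles convergence
            new_order, _, _ = _greedy(engine, orders[c], other, logf[c],
                                      max_passes=1)
            if not np.array_equal(new_order, orders[c]):
                changed = True
                orders[c] = new_order
                sll[c] = _subject_ll_batch(engine, new_order[None, :])[0]
        new_ll = _mixture_ll(sll, fractions)
        trace.append(new_ll)
        converged = not changed and new_ll - ll < tol
        ll = max(ll, new_ll)
        if converged:
            break
    return orders, fractions, ll, trace


def update_fractions(data: BiomarkerDataset, model: SubtypeMixtureModel,
                     quadrature_points: int = 10) -> np.ndarray:
    """One E-M M-step for the fractions: mean per-subject subtype posterior."""
    _, posterior = mixture_log_likelihood(data, model, quadrature_points)
    f = posterior.mean(axis=0)
    return f / f.sum()


def split_cluster_em(data: BiomarkerDataset, model: SubtypeMixtureModel,
                     cluster: int, n_restarts: int = 25,
                     seed: int | None = None, quadrature_points: int = 10,
                     em_tol: float = 1e-6, em_max_iter: int = 100,
                     ) -> FitResult | None:
    """Candidate (C+1)-subtype model obtained by splitting one cluster.

    Subjects hard-assigned to the cluster are randomly bipartitioned; each
    half gets a greedy single-sequence fit, the pair initialises a
    two-cluster E-M on the cluster's subjects, and the resulting pair
    replaces the split cluster before a full-model E-M refinement.  The best
    of ``n_restarts`` random bipartitions is returned; ``None`` signals an
    infeasible split (fewer than two hard-assigned subjects).
    """
    _, posterior = mixture_log_likelihood(data, model, quadrature_points)
    hard = np.argmax(posterior, axis=1)
    members = np.flatnonzero(hard == cluster)
    if len(members) < 2:
        return None
    eng_full = LikelihoodEngine(data, model.event_set, model.noise,
                                quadrature_points)
    sub_data = data.subset(members)
    eng_sub = LikelihoodEngine(sub_data, model.event_set, model.noise,
                               quadrature_points)
    other_orders = [model.sequences[c].order for c in range(model.n_subtypes)
                    if c != cluster]
    other_fracs = [model.fractions[c] for c in range(model.n_subtypes)
                   if c != cluster]
    f_c = model.fractions[cluster]

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best: tuple[float, list[np.ndarray], np.ndarray] | None = None
    restart_lls = []
    for ss in children:
        rng = np.random.default_rng(ss)
        # random bipartition of the cluster's subjects, both halves non-empty
        grp = rng.integers(0, 2, len(members))
        if grp.min() == grp.max():
            grp[rng.integers(len(members))] = 1 - grp[0]
        halves = []
        for g in (0, 1):
            half = sub_data.subset(grp == g)
            eng_half = LikelihoodEngine(half, model.event_set, model.noise,
                                        quadrature_points)
            start = random_admissible_sequence(model.event_set, rng)
            order, _, _ = _greedy(eng_half, start.order)
            halves.append(order)
        g1 = np.mean(grp == 0)
        pair, pair_f, _, _ = _em_refine(eng_sub, halves,
                                        np.array([g1, 1.0 - g1]),
                                        em_tol, em_max_iter)
        orders = list(other_orders) + list(pair)
        fracs = np.array(list(other_fracs) + [f_c * pair_f[0], f_c * pair_f[1]])
        fracs = fracs / fracs.sum()
        orders, fracs, ll, _ = _em_refine(eng_full, orders, fracs,
                                          em_tol, em_max_iter)
        restart_lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, orders, fracs)
    ll, orders, fracs = best
    new_model = SubtypeMixtureModel(
        model.event_set, [SubtypeSequence(o) for o in orders], fracs,
        model.noise)
    return FitResult(new_model, ll, restart_lls, seed,
                     meta={"split_cluster": cluster, "n_restarts": n_restarts})


def fit_hierarchical(data: BiomarkerDataset, event_set: ZScoreEventSet,
                     noise: NoiseModel | None = None, c_max: int = 3,
                     n_restarts: int = 25, seed: int | None = None,
                     quadrature_points: int = 10, em_tol: float = 1e-6,
                     em_max_iter: int = 100) -> list[FitResult]:
    """Fit models with 1..c_max subtypes, each initialised from the last.

    Each C-subtype model is the best of the candidates obtained by
    splitting each of the previous model's clusters in turn; the in-sample
    likelihood is therefore non-decreasing in C.  If no cluster can be
    split the list is truncated with a warning.
    """
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    noise = noise or NoiseModel.unit(event_set.n_biomarkers)
    master = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 master.spawn(c_max)]
    # C=1 uses the caller's seed directly so the stages-only special case
    # reproduces it exactly
    results = [fit_single_cluster(data, event_set, noise, n_restarts,
                                  seed, quadrature_points)]
    for C in range(2, c_max + 1):
        prev = results[-1].model
        best: FitResult | None = None
        for c in range(prev.n_subtypes):
            cand = split_cluster_em(data, prev, c, n_restarts,
                                    sub_seeds[C - 1] + c, quadrature_points,
                                    em_tol, em_max_iter)
            if cand is not None and (best is None
                                     or cand.log_likelihood > best.log_likelihood):
                best = cand
        if best is None:
            warnings.warn(f"no feasible split at C={C}; stopping early")
            break
        best.seed = seed
        results.append(best)
    return results
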