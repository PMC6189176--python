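"""Generative model for subtype and stage inference.

A cohort is modelled as a mixture of *linear z-score models*: each subtype
is a sequence of z-score events, where an event is a biomarker reaching a
z-score threshold (relative to controls).  Between events each biomarker's
mean follows a piecewise-linear trajectory g_i(t) over an arbitrary model
time t in [0, 1], starting at 0 and ending at the biomarker's maximum
z-score.  Observations are the trajectory value at the subject's (latent,
uniformly distributed) disease time plus Gaussian noise, and the likelihood
integrates the latent time out stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as _Seq

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BiomarkerDataset",
    "ZScoreEventSet",
    "SubtypeSequence",
    "NoiseModel",
    "SubtypeMixtureModel",
    "StageGrid",
    "event_times",
    "trajectory_value",
    "stage_likelihood_matrix",
    "sequence_log_likelihood",
    "mixture_log_likelihood",
    "is_admissible",
    "random_admissible_sequence",
    "enumerate_admissible_sequences",
    "LikelihoodEngine",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerDataset:
    """Subjects x biomarkers table of z-scores.

    Missing entries are flagged as NaN and are marginalised out of the
    likelihood (they contribute a factor of one).  ``labels`` carries
    per-subject categorical tags (diagnosis, genotype) that are never used
    in fitting.
    """

    values: np.ndarray
    biomarker_names: list[str]
    subject_ids: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x biomarkers array")
        if self.values.shape[1] != len(self.biomarker_names):
            raise ValueError("number of biomarker names must match columns")
        if len(set(self.biomarker_names)) != len(self.biomarker_names):
            raise ValueError("biomarker names must be unique")
        if self.subject_ids is None:
            self.subject_ids = [f"s{j}" for j in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("number of subject ids must match rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels must have one entry per subject")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def select_biomarkers(self, names: _Seq[str]) -> "BiomarkerDataset":
        """Return a dataset restricted to ``names`` (in the given order)."""
        idx = [self.biomarker_names.index(n) for n in names]
        return BiomarkerDataset(
            self.values[:, idx], list(names), list(self.subject_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def subset(self, rows: np.ndarray) -> "BiomarkerDataset":
        """Return a dataset restricted to the given subject rows."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return BiomarkerDataset(
            self.values[rows],
            list(self.biomarker_names),
            [self.subject_ids[j] for j in rows],
            None if self.labels is None else self.labels[rows],
        )


@dataclass
class ZScoreEventSet:
    """The N z-score events: per biomarker, increasing thresholds and a cap.

    ``z_scores[i]`` holds the strictly increasing positive thresholds of
    biomarker i; ``z_max[i]`` is the value the trajectory reaches at t = 1
    and must exceed the largest threshold.  Events are indexed 0..N-1 in
    biomarker-major order.
    """

    biomarker_names: list[str]
    z_scores: list[np.ndarray]
    z_max: np.ndarray

    # derived event table
    event_biomarker: np.ndarray = field(init=False)
    event_z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z_scores = [np.asarray(z, dtype=float) for z in self.z_scores]
        self.z_max = np.asarray(self.z_max, dtype=float)
        if not (len(self.biomarker_names) == len(self.z_scores) == len(self.z_max)):
            raise ValueError("biomarker_names, z_scores and z_max must align")
        for i, z in enumerate(self.z_scores):
            if len(z) == 0:
                raise ValueError(f"biomarker {self.biomarker_names[i]} has no events")
            if np.any(z <= 0) or np.any(np.diff(z) <= 0):
                raise ValueError("z-scores must be strictly positive and increasing")
            if self.z_max[i] <= z[-1]:
                raise ValueError("z_max must exceed the largest retained z-score")
        self.event_biomarker = np.concatenate(
            [np.full(len(z), i, dtype=int) for i, z in enumerate(self.z_scores)]
        )
        self.event_z = np.concatenate(self.z_scores)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_names)

    @property
    def n_events(self) -> int:
        return len(self.event_z)

    def biomarker_events(self, i: int) -> np.ndarray:
        """Event indices of biomarker i, in increasing-z order."""
        return np.flatnonzero(self.event_biomarker == i)

    @classmethod
    def uniform(cls, biomarker_names: _Seq[str], z: _Seq[float] = (1.0, 2.0, 3.0),
                z_max: float = 5.0) -> "ZScoreEventSet":
        """Same thresholds and cap for every biomarker."""
        n = len(biomarker_names)
        return cls(list(biomarker_names), [np.asarray(z, float)] * n,
                   np.full(n, float(z_max)))


@dataclass
class SubtypeSequence:
    """One ordering of the N events: ``order[k]`` is the event at position k.

    The event at position k (0-based) completes at model time
    (k + 1) / (N + 1); stage k means the first k events have completed.
    """

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        n = len(self.order)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of 0..N-1")

    @property
    def n_events(self) -> int:
        return len(self.order)

    def positions(self) -> np.ndarray:
        """Position of each event: inverse permutation of ``order``."""
        pos = np.empty(self.n_events, dtype=int)
        pos[self.order] = np.arange(self.n_events)
        return pos


@dataclass
class NoiseModel:
    """Per-biomarker observation noise, in z-score standard deviations."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @classmethod
    def unit(cls, n_biomarkers: int) -> "NoiseModel":
        return cls(np.ones(n_biomarkers))


@dataclass
class SubtypeMixtureModel:
    """A mixture of C linear z-score models sharing one event set."""

    event_set: ZScoreEventSet
    sequences: list[SubtypeSequence]
    fractions: np.ndarray
    noise: NoiseModel

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one fraction per subtype required")
        if len(self.sequences) < 1:
            raise ValueError("at least one subtype required")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-10:
            raise ValueError("fractions must be non-negative and sum to 1")
        n = self.event_set.n_events
        for s in self.sequences:
            if s.n_events != n:
                raise ValueError("all sequences must cover the shared event set")
        if len(self.noise.sigma) != self.event_set.n_biomarkers:
            raise ValueError("noise must have one sigma per biomarker")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)


@dataclass
class StageGrid:
    """The N+1 discrete stages and the uniform priors over stage and time.

    Stage k spans model time [k/(N+1), (k+1)/(N+1)); the prior over stages
    is uniform, 1/(N+1), matching a uniform prior density P(t) = 1 on [0, 1].
    """

    n_events: int

    @property
    def n_stages(self) -> int:
        return self.n_events + 1

    @property
    def boundaries(self) -> np.ndarray:
        return np.arange(self.n_stages + 1) / (self.n_events + 1)

    @property
    def stage_prior(self) -> np.ndarray:
        return np.full(self.n_stages, 1.0 / self.n_stages)


# ---------------------------------------------------------------------------
# Event times and trajectories
# ---------------------------------------------------------------------------

def event_times(sequence: SubtypeSequence, n_events: int | None = None) -> np.ndarray:
    """Model time at which each event completes, ordered by position.

    The event at position k (0-based) completes at (k + 1) / (N + 1), so the
    returned array is strictly increasing in (0, 1).
    """
    n = sequence.n_events
    if n_events is not None and n_events != n:
        raise ValueError(f"sequence has {n} events, expected {n_events}")
    return (np.arange(n) + 1.0) / (n + 1.0)


def _trajectory_knots(event_set: ZScoreEventSet, positions: np.ndarray,
                      biomarker: int) -> tuple[np.ndarray, np.ndarray]:
    n = event_set.n_events
    idx = event_set.biomarker_events(biomarker)
    t_ev = (positions[idx] + 1.0) / (n + 1.0)
    tk = np.concatenate(([0.0], t_ev, [1.0]))
    vk = np.concatenate(([0.0], event_set.z_scores[biomarker],
                         [event_set.z_max[biomarker]]))
    return tk, vk


def trajectory_value(event_set: ZScoreEventSet, sequence: SubtypeSequence,
                     biomarker: int, t: float | np.ndarray) -> np.ndarray | float:
    """Piecewise-linear mean trajectory g_i(t) of one biomarker.

    g_i rises linearly from 0 through each (event time, z-score) knot and on
    to (1, z_max); it is continuous and non-decreasing.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("model time t must lie in [0, 1]")
    tk, vk = _trajectory_knots(event_set, sequence.positions(), biomarker)
    out = np.interp(t_arr, tk, vk)
    return float(out) if np.isscalar(t) else out


def _trajectory_matrix(event_set: ZScoreEventSet, order: np.ndarray,
                       tgrid: np.ndarray) -> np.ndarray:
    """(I, T) matrix of g_i(t) on a time grid, for one event ordering."""
    n = len(order)
    positions = np.empty(n, dtype=int)
    positions[order] = np.arange(n)
    mus = np.empty((event_set.n_biomarkers, len(tgrid)))
    for i in range(event_set.n_biomarkers):
        tk, vk = _trajectory_knots(event_set, positions, i)
        mus[i] = np.interp(tgrid, tk, vk)
    return mus


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Precomputed quantities for fast stage-likelihood evaluation.

    The per-subject log density at a grid time t decomposes as
    sum_i [a_ij + (x_ij / sigma_i^2) mu_i(t) - mu_i(t)^2 / (2 sigma_i^2)],
    so evaluating all subjects on all grid points is two matrix products.
    Missing (NaN) entries contribute zero to every term.

    The latent-time integral over each stage interval uses a composite
    midpoint rule with ``quadrature_points`` points per stage.
    """

    def __init__(self, data: BiomarkerDataset, event_set: ZScoreEventSet,
                 noise: NoiseModel, quadrature_points: int = 10) -> None:
        if event_set.n_biomarkers != data.n_biomarkers:
            raise ValueError("event set and dataset biomarkers must align")
        if len(noise.sigma) != data.n_biomarkers:
            raise ValueError("noise must have one sigma per biomarker")
        if quadrature_points < 1:
            raise ValueError("quadrature_points must be >= 1")
        self.event_set = event_set
        self.noise = noise
        self.quadrature_points = int(quadrature_points)
        self.n_events = event_set.n_events
        self.n_stages = self.n_events + 1

        x = np.asarray(data.values, dtype=float)
        mask = np.isfinite(x)
        if x.size and not mask.all():
            # NaN means missing; +/-inf is malformed input
            if np.any(np.isinf(x)):
                raise ValueError("non-finite values other than NaN in data")
        xz = np.where(mask, x, 0.0)
        s2 = noise.sigma ** 2
        self.n_subjects = x.shape[0]
        self._const = np.sum(
            np.where(mask, -0.5 * np.log(2 * np.pi * s2) - 0.5 * xz ** 2 / s2, 0.0),
            axis=1,
        )                                       # (J,)
        self._lin = np.where(mask, xz / s2, 0.0)        # (J, I)
        self._quad = np.where(mask, 0.5 / s2, 0.0)      # (J, I)

        K = self.quadrature_points
        self.tgrid = (np.arange(self.n_stages * K) + 0.5) / (self.n_stages * K)
        # log of midpoint-rule weight: interval width / K, with P(t) = 1
        self._log_weight = -np.log(K) - np.log(self.n_stages)

    def grid_log_density(self, mus: np.ndarray) -> np.ndarray:
        """(J, T) log prod_i P(x_ij | t) for trajectory values ``mus`` (I, T)."""
        return self._const[:, None] + self._lin @ mus - self._quad @ (mus ** 2)

    @staticmethod
    def _logsumexp_last(a: np.ndarray) -> np.ndarray:
        # in-place-friendly logsumexp over the trailing axis (hot path)
        m = a.max(axis=-1)
        np.subtract(a, m[..., None], out=a)
        np.exp(a, out=a)
        return m + np.log(a.sum(axis=-1))

    def stage_log_likelihood(self, order: np.ndarray) -> np.ndarray:
        """(J, N+1) log of the per-stage integral of P(t) prod_i P(x_ij | t)."""
        mus = _trajectory_matrix(self.event_set, order, self.tgrid)
        ll = self.grid_log_density(mus)
        K = self.quadrature_points
        ll = ll.reshape(self.n_subjects, self.n_stages, K)
        return self._logsumexp_last(ll) + self._log_weight

    def stage_log_likelihood_batch(self, orders: np.ndarray) -> np.ndarray:
        """(B, J, N+1) stage log-likelihoods for a batch of orderings."""
        orders = np.asarray(orders)
        B = orders.shape[0]
        T = len(self.tgrid)
        mus = np.empty((self.event_set.n_biomarkers, B * T))
        for b in range(B):
            mus[:, b * T:(b + 1) * T] = _trajectory_matrix(
                self.event_set, orders[b], self.tgrid)
        ll = self.grid_log_density(mus)                  # (J, B*T)
        K = self.quadrature_points
        ll = ll.reshape(self.n_subjects, B, self.n_stages, K)
        out = self._logsumexp_last(ll) + self._log_weight  # (J, B, N+1)
        return np.ascontiguousarray(np.moveaxis(out, 1, 0))

    def subject_log_likelihood(self, order: np.ndarray) -> np.ndarray:
        """(J,) log P(x_j | S): stage integrals summed over stages.

        Because the midpoint weight is the same for every stage, this is a
        single logsumexp over the whole time grid.
        """
        mus = _trajectory_matrix(self.event_set, order, self.tgrid)
        ll = self.grid_log_density(mus)
        return self._logsumexp_last(ll) + self._log_weight

    def subject_log_likelihood_batch(self, orders: np.ndarray) -> np.ndarray:
        """(B, J) per-subject log P(x_j | S) for a batch of orderings."""
        orders = np.asarray(orders)
        B = orders.shape[0]
        T = len(self.tgrid)
        mus = np.empty((self.event_set.n_biomarkers, B * T))
        for b in range(B):
            mus[:, b * T:(b + 1) * T] = _trajectory_matrix(
                self.event_set, orders[b], self.tgrid)
        ll = self.grid_log_density(mus).reshape(self.n_subjects, B, T)
        out = self._logsumexp_last(ll) + self._log_weight   # (J, B)
        return out.T.copy()


# ---------------------------------------------------------------------------
# Public likelihood operations
# ---------------------------------------------------------------------------

def stage_likelihood_matrix(data: BiomarkerDataset, sequence: SubtypeSequence,
                            event_set: ZScoreEventSet, noise: NoiseModel,
                            quadrature_points: int = 10) -> np.ndarray:
    """J x (N+1) matrix of per-stage data likelihoods.

    Entry (j, k) approximates the integral of P(t) prod_i P(x_ij | t) over
    stage k's time interval.
    """
    eng = LikelihoodEngine(data, event_set, noise, quadrature_points)
    return np.exp(eng.stage_log_likelihood(sequence.order))


def sequence_log_likelihood(data: BiomarkerDataset, sequence: SubtypeSequence,
                            event_set: ZScoreEventSet, noise: NoiseModel,
                            quadrature_points: int = 10,
                            ) -> tuple[float, np.ndarray]:
    """Total log P(X | S) and the per-subject posterior over stages."""
    eng = LikelihoodEngine(data, event_set, noise, quadrature_points)
    stage_ll = eng.stage_log_likelihood(sequence.order)
    subj_ll = logsumexp(stage_ll, axis=1)
    posterior = np.exp(stage_ll - subj_ll[:, None])
    return float(subj_ll.sum()), posterior


def mixture_log_likelihood(data: BiomarkerDataset, model: SubtypeMixtureModel,
                           quadrature_points: int = 10,
                           ) -> tuple[float, np.ndarray]:
    """Total log P(X | M) under the subtype mixture and the per-subject
    posterior over subtypes.

    With a single subtype this reduces exactly to
    :func:`sequence_log_likelihood`.
    """
    eng = LikelihoodEngine(data, model.event_set, model.noise, quadrature_points)
    C = model.n_subtypes
    comp = np.empty((eng.n_subjects, C))
    for c in range(C):
        comp[:, c] = eng.subject_log_likelihood(model.sequences[c].order)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    joint = comp + logf[None, :]
    subj_ll = logsumexp(joint, axis=1)
    posterior = np.exp(joint - subj_ll[:, None])
    return float(subj_ll.sum()), posterior


# ---------------------------------------------------------------------------
# Admissible orderings
# ---------------------------------------------------------------------------
# A sequence is admissible when, within each biomarker, lower z-score events
# precede higher ones: the monotone trajectory makes any other order
# meaningless.

def is_admissible(order: np.ndarray, event_set: ZScoreEventSet) -> bool:
    order = np.asarray(order)
    pos = np.empty(len(order), dtype=int)
    pos[order] = np.arange(len(order))
    for i in range(event_set.n_biomarkers):
        idx = event_set.biomarker_events(i)
        if np.any(np.diff(pos[idx]) <= 0):
            return False
    return True


def random_admissible_sequence(event_set: ZScoreEventSet,
                               rng: np.random.Generator) -> SubtypeSequence:
    """Uniform draw over admissible orderings.

    A uniformly random permutation is made admissible by sorting each
    biomarker's events into increasing-z order within the positions they
    occupy; every admissible ordering corresponds to the same number of raw
    permutations, so the draw is uniform over the admissible set.
    """
    n = event_set.n_events
    order = rng.permutation(n)
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    for i in range(event_set.n_biomarkers):
        idx = event_set.biomarker_events(i)          # increasing z
        slots = np.sort(pos[idx])
        pos[idx] = slots
    out = np.empty(n, dtype=int)
    out[pos] = np.arange(n)
    return SubtypeSequence(out)


def enumerate_admissible_sequences(event_set: ZScoreEventSet) -> list[np.ndarray]:
    """All admissible orderings (use only for small event sets)."""
    from itertools import permutations

    n = event_set.n_events
    out = []
    for perm in permutations(range(n)):
        order = np.array(perm)
        if is_admissible(order, event_set):
            out.append(order)
    return out
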