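"""MCMC uncertainty over subtype sequences and mixture fractions.

The posterior over event orderings is explored with a Metropolis-Hastings
chain under a flat prior on admissible sequences: each step relocates one
randomly chosen event of one randomly chosen subtype to a uniformly random
admissible position (a symmetric proposal), optionally jointly perturbing
the mixture fractions, and accepts by likelihood ratio.  The chain starts
at the maximum-likelihood solution.  Positional summaries (the probability
of each event at each position) feed the positional variance diagram and
the cumulative severity colour encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    BiomarkerDataset,
    LikelihoodEngine,
    SubtypeMixtureModel,
    ZScoreEventSet,
)
from .fitting import _candidate_orders

__all__ = [
    "MCMCSamples",
    "PositionalDistribution",
    "mcmc_sample",
    "positional_distribution",
    "cumulative_severity_encoding",
    "log_likelihood_autocorrelation",
]


@dataclass
class MCMCSamples:
    """Posterior draws of the model: sequences, fractions, log-likelihoods."""

    sequences: np.ndarray        # (n_samples, C, N) event indices
    fractions: np.ndarray        # (n_samples, C)
    log_likelihoods: np.ndarray  # (n_samples,)
    acceptance_rate: float
    seed: int | None = None
    thin: int = 1

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_subtypes(self) -> int:
        return self.sequences.shape[1]

    @property
    def n_events(self) -> int:
        return self.sequences.shape[2]


@dataclass
class PositionalDistribution:
    """Per-subtype event x position probability matrices (N x N).

    Row e gives the distribution of event e's position over the samples, so
    every row sums to one; columns sum to one in expectation because each
    sampled sequence is a permutation.
    """

    probabilities: np.ndarray    # (C, N, N)

    @property
    def n_subtypes(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_events(self) -> int:
        return self.probabilities.shape[1]

    def subtype(self, c: int) -> np.ndarray:
        return self.probabilities[c]


def _fast_logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.sum(np.exp(a - m), axis=axis))
    return out


def mcmc_sample(data: BiomarkerDataset, model: SubtypeMixtureModel,
                n_samples: int = 1_000_000, seed: int | None = None,
                sample_fractions: bool = True, fraction_step: float = 0.01,
                thin: int = 1, burn_in: int = 0,
                quadrature_points: int = 10) -> MCMCSamples:
    """Metropolis-Hastings sampling of sequences (and fractions).

    ``n_samples`` counts chain steps; one state is stored every ``thin``
    steps after ``burn_in``.  There is no burn-in by default because the
    chain starts at the maximum-likelihood solution.  With a fixed seed the
    sample stream is reproducible.
    """
    rng = np.random.default_rng(seed)
    eng = LikelihoodEngine(data, model.event_set, model.noise,
                           quadrature_points)
    C = model.n_subtypes
    N = model.event_set.n_events
    orders = [s.order.copy() for s in model.sequences]
    fractions = model.fractions.copy()

    def subject_ll(order: np.ndarray) -> np.ndarray:
        return eng.subject_log_likelihood(order)

    sll = np.stack([subject_ll(o) for o in orders])   # (C, J)

    def total_ll(sll_mat: np.ndarray, f: np.ndarray) -> float:
        if C == 1:
            return float(sll_mat[0].sum())
        with np.errstate(divide="ignore"):
            logf = np.log(f)
        return float(_fast_logsumexp(logf[:, None] + sll_mat, axis=0).sum())

    cur_ll = total_ll(sll, fractions)

    n_keep = max(0, (n_samples - burn_in + thin - 1) // thin)
    seq_store = np.empty((n_keep, C, N), dtype=np.int16)
    frac_store = np.empty((n_keep, C))
    ll_store = np.empty(n_keep)
    accepted = 0
    kept = 0
    for step in range(n_samples):
        c = int(rng.integers(C))
        event = int(rng.integers(N))
        cands = _candidate_orders(orders[c], event, model.event_set)
        prop_order = cands[int(rng.integers(len(cands)))]
        if sample_fractions and C > 1:
            prop_f = fractions + rng.normal(0.0, fraction_step, C)
            prop_f = np.clip(prop_f, 0.0, None)
            total = prop_f.sum()
            prop_f = prop_f / total if total > 0 else fractions
        else:
            prop_f = fractions
        new_sll_c = subject_ll(prop_order)
        old_row = sll[c].copy()
        sll[c] = new_sll_c
        prop_ll = total_ll(sll, prop_f)
        if np.log(rng.uniform()) < prop_ll - cur_ll:
            orders[c] = prop_order
            fractions = prop_f
            cur_ll = prop_ll
            accepted += 1
        else:
            sll[c] = old_row
        if step >= burn_in and (step - burn_in) % thin == 0:
            seq_store[kept] = np.stack(orders)
            frac_store[kept] = fractions
            ll_store[kept] = cur_ll
            kept += 1
    if n_samples > 0 and accepted == 0:
        warnings.warn(
            "MCMC accepted no proposals; the chain did not move. "
            f"(chain length {n_samples}, single-event relocation proposal)")
    return MCMCSamples(seq_store[:kept], frac_store[:kept], ll_store[:kept],
                       accepted / max(n_samples, 1), seed, thin)


def positional_distribution(samples: MCMCSamples) -> PositionalDistribution:
    """Empirical probability of each event at each position, per subtype."""
    if samples.n_samples == 0:
        raise ValueError("cannot summarise an empty sample set")
    C, N = samples.n_subtypes, samples.n_events
    probs = np.empty((C, N, N))
    pos_idx = np.arange(N)
    for c in range(C):
        seqs = samples.sequences[:, c, :].astype(np.int64)   # (S, N)
        flat = (seqs * N + pos_idx[None, :]).ravel()
        counts = np.bincount(flat, minlength=N * N).reshape(N, N)
        probs[c] = counts / samples.n_samples
    return PositionalDistribution(probs)


def cumulative_severity_encoding(pos: PositionalDistribution,
                                 event_set: ZScoreEventSet, stage: int,
                                 subtype: int = 0) -> np.ndarray:
    """Per-biomarker colour-channel weights at a stage.

    Channel r of biomarker i is the posterior probability that its r-th
    z-score event (z = 1, 2, 3 under the usual threshold set) has completed
    by the given stage, i.e. sits at a position before ``stage``.  Weights
    are in [0, 1], non-decreasing in stage, and map onto the
    white -> red -> magenta -> blue rendering of increasing severity.
    """
    N = pos.n_events
    if not 0 <= stage <= N:
        raise ValueError("stage must be in 0..N")
    mat = pos.subtype(subtype)
    out = np.zeros((event_set.n_biomarkers, 3))
    for i in range(event_set.n_biomarkers):
        for r, e in enumerate(event_set.biomarker_events(i)[:3]):
            out[i, r] = mat[e, :stage].sum()
    return out


def log_likelihood_autocorrelation(samples: MCMCSamples, lag: int = 100) -> float:
    """Lag autocorrelation of the chain's log-likelihood trace.

    A mixing diagnostic: values near zero indicate the chain decorrelates
    quickly relative to the lag.
    """
    x = samples.log_likelihoods
    if len(x) <= lag:
        raise ValueError("chain shorter than the requested lag")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    return float(np.dot(x[:-lag], x[lag:]) / denom)
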