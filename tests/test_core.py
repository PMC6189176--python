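"""Generative-model unit tests: event times, trajectories, likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import substage as ss
from substage.core import LikelihoodEngine, _trajectory_matrix

from conftest import make_dataset, sequential_sequence


# ---------------------------------------------------------------------------
# Event-time mapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, position, expected", [
    (2, 0, 1.0 / 3.0),
    (2, 1, 2.0 / 3.0),
    (1, 0, 0.5),
    (4, 3, 4.0 / 5.0),
])
def test_event_time_of_position(n, position, expected):
    """The event at position k completes at time (k+1)/(N+1)."""
    times = ss.event_times(sequential_sequence(n))
    assert times[position] == pytest.approx(expected, abs=1e-12)


def test_event_times_strictly_increasing_and_validated():
    times = ss.event_times(sequential_sequence(7))
    assert np.all(np.diff(times) > 0)
    assert np.all((times > 0) & (times < 1))
    with pytest.raises(ValueError):
        ss.event_times(sequential_sequence(3), n_events=4)
    with pytest.raises(ValueError):
        ss.SubtypeSequence([0, 0, 1])


# ---------------------------------------------------------------------------
# Piecewise-linear trajectory
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t, expected", [
    (1.0 / 6.0, 0.5),   # midpoint of the rise to z=1
    (0.5, 1.5),         # midpoint between z=1 and z=2
    (1.0, 3.0),         # endpoint hits z_max
    (0.0, 0.0),
])
def test_trajectory_examples(single_biomarker_events, t, expected):
    seq = sequential_sequence(2)   # z=1 at t=1/3, z=2 at t=2/3
    assert ss.trajectory_value(single_biomarker_events, seq, 0, t) == \
        pytest.approx(expected, abs=1e-12)


def test_trajectory_rejects_time_outside_unit_interval(single_biomarker_events):
    seq = sequential_sequence(2)
    with pytest.raises(ValueError):
        ss.trajectory_value(single_biomarker_events, seq, 0, 1.2)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_trajectory_monotone_and_through_knots(seed):
    """g_i is non-decreasing, g_i(0)=0, g_i(1)=z_max, and hits every event."""
    rng = np.random.default_rng(seed)
    es = ss.ZScoreEventSet.uniform(["p", "q"], z=(1.0, 2.0, 3.0), z_max=5.0)
    seq = ss.random_admissible_sequence(es, rng)
    times = ss.event_times(seq)
    pos = seq.positions()
    for i in range(es.n_biomarkers):
        tgrid = np.linspace(0, 1, 101)
        g = ss.trajectory_value(es, seq, i, tgrid)
        assert np.all(np.diff(g) >= -1e-12)
        assert g[0] == 0.0
        assert g[-1] == pytest.approx(es.z_max[i])
        for e, z in zip(es.biomarker_events(i), es.z_scores[i]):
            assert ss.trajectory_value(es, seq, i, times[pos[e]]) == \
                pytest.approx(z, abs=1e-12)


# ---------------------------------------------------------------------------
# Stage likelihood matrix
# ---------------------------------------------------------------------------

def test_stage_likelihood_quadrature_convergence(rng):
    """K=100 and K=1000 midpoint rules agree to < 1e-4 per entry."""
    es = ss.ZScoreEventSet.uniform(["a", "b", "c"], z=(1.0, 2.0), z_max=3.0)
    seq = ss.random_admissible_sequence(es, rng)
    cfg = ss.SimulationConfig(event_set=es, sequences=[seq],
                              fractions=np.array([1.0]), n_subjects=8,
                              sigma=1.0, seed=3)
    data, _, _ = ss.simulate_cohort(cfg)
    noise = ss.NoiseModel.unit(3)
    coarse = ss.stage_likelihood_matrix(data, seq, es, noise,
                                        quadrature_points=100)
    fine = ss.stage_likelihood_matrix(data, seq, es, noise,
                                      quadrature_points=1000)
    rel = np.abs(coarse - fine) / fine
    assert rel.max() < 1e-4


def test_stage_likelihood_peaks_at_generating_stage(rng):
    """A subject lying exactly on the trajectory at a stage midpoint is
    staged there under small noise."""
    es = ss.ZScoreEventSet.uniform(["a", "b"], z=(1.0, 2.0), z_max=3.0)
    seq = ss.random_admissible_sequence(es, rng)
    n = es.n_events
    noise = ss.NoiseModel(np.full(2, 0.1))
    for k in [0, 2, n]:
        t_mid = (k + 0.5) / (n + 1)
        x = [ss.trajectory_value(es, seq, i, t_mid) for i in range(2)]
        mat = ss.stage_likelihood_matrix(make_dataset([x], ["a", "b"]),
                                         seq, es, noise)
        assert np.argmax(mat[0]) == k


def test_all_zero_subject_stages_at_zero(single_biomarker_events):
    seq = sequential_sequence(2)
    mat = ss.stage_likelihood_matrix(make_dataset([[0.0]], ["bm0"]), seq,
                                     single_biomarker_events,
                                     ss.NoiseModel.unit(1))
    assert np.argmax(mat[0]) == 0
    assert np.all(mat >= 0) and np.all(np.isfinite(mat))


def test_stage_likelihood_rejects_bad_sigma(single_biomarker_events):
    with pytest.raises(ValueError):
        ss.NoiseModel(np.array([0.0]))
    with pytest.raises(ValueError):
        ss.stage_likelihood_matrix(
            make_dataset([[np.inf]], ["bm0"]), sequential_sequence(2),
            single_biomarker_events, ss.NoiseModel.unit(1))


# ---------------------------------------------------------------------------
# Sequence log-likelihood
# ---------------------------------------------------------------------------

def trapezoid_log_likelihood(values, es, seq, sigma, n_points=100_001):
    """Independent oracle: trapezoid rule over the full latent-time axis."""
    t = np.linspace(0.0, 1.0, n_points)
    total = 0.0
    for x in np.atleast_2d(values):
        dens = np.ones_like(t)
        for i, xi in enumerate(x):
            if not np.isfinite(xi):
                continue
            g = ss.trajectory_value(es, seq, i, t)
            dens *= np.exp(-0.5 * ((xi - g) / sigma[i]) ** 2) / (
                sigma[i] * np.sqrt(2 * np.pi))
        total += np.log(np.trapezoid(dens, t))
    return total


def test_sequence_log_likelihood_matches_trapezoid_oracle(
        single_biomarker_events):
    """J=1, N=1-style small case agrees with dense numerical integration."""
    seq = sequential_sequence(2)
    data = make_dataset([[1.3]], ["bm0"])
    noise = ss.NoiseModel.unit(1)
    ll, post = ss.sequence_log_likelihood(data, seq, single_biomarker_events,
                                          noise, quadrature_points=200)
    oracle = trapezoid_log_likelihood(data.values, single_biomarker_events,
                                      seq, noise.sigma)
    assert ll == pytest.approx(oracle, rel=1e-6)
    assert post.shape == (1, 3)


def test_duplicating_subjects_doubles_log_likelihood(rng, three_flat_events):
    seq = sequential_sequence(3)
    x = rng.normal(0.5, 1.0, size=(6, 3))
    noise = ss.NoiseModel.unit(3)
    ll1, _ = ss.sequence_log_likelihood(make_dataset(x), seq,
                                        three_flat_events, noise)
    ll2, _ = ss.sequence_log_likelihood(make_dataset(np.vstack([x, x])), seq,
                                        three_flat_events, noise)
    assert ll2 == pytest.approx(2 * ll1, abs=1e-9)


def test_log_likelihood_invariant_to_subject_order(rng, three_flat_events):
    seq = sequential_sequence(3)
    x = rng.normal(0.5, 1.0, size=(10, 3))
    noise = ss.NoiseModel.unit(3)
    ll1, _ = ss.sequence_log_likelihood(make_dataset(x), seq,
                                        three_flat_events, noise)
    ll2, _ = ss.sequence_log_likelihood(make_dataset(x[::-1]), seq,
                                        three_flat_events, noise)
    assert ll1 == pytest.approx(ll2, abs=1e-9)


def test_stage_posterior_rows_are_distributions(rng, three_flat_events):
    seq = sequential_sequence(3)
    x = rng.normal(0.0, 2.0, size=(12, 3))
    _, post = ss.sequence_log_likelihood(make_dataset(x), seq,
                                         three_flat_events,
                                         ss.NoiseModel.unit(3))
    assert np.all(post >= 0)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_missing_values_marginalised_out(three_flat_events):
    """A NaN entry contributes a factor of one; an all-NaN subject has
    log-likelihood zero."""
    seq = sequential_sequence(3)
    noise = ss.NoiseModel.unit(3)
    x = np.array([[np.nan, np.nan, np.nan]])
    ll, _ = ss.sequence_log_likelihood(make_dataset(x), seq,
                                       three_flat_events, noise)
    assert ll == pytest.approx(0.0, abs=1e-12)
    # NaN in one biomarker: other biomarkers' values still matter,
    # the missing one does not
    a = np.array([[0.5, np.nan, 1.0]])
    b = np.array([[0.5, np.nan, 2.0]])
    lla, _ = ss.sequence_log_likelihood(make_dataset(a), seq,
                                        three_flat_events, noise)
    llb, _ = ss.sequence_log_likelihood(make_dataset(b), seq,
                                        three_flat_events, noise)
    assert lla != pytest.approx(llb)


# ---------------------------------------------------------------------------
# Mixture likelihood
# ---------------------------------------------------------------------------

def test_mixture_with_one_subtype_equals_sequence_likelihood(
        rng, three_flat_events):
    seq = sequential_sequence(3)
    x = rng.normal(0.5, 1.0, size=(9, 3))
    noise = ss.NoiseModel.unit(3)
    model = ss.SubtypeMixtureModel(three_flat_events, [seq],
                                   np.array([1.0]), noise)
    ll_mix, post = ss.mixture_log_likelihood(make_dataset(x), model)
    ll_seq, _ = ss.sequence_log_likelihood(make_dataset(x), seq,
                                           three_flat_events, noise)
    assert ll_mix == ll_seq
    np.testing.assert_array_equal(post, np.ones((9, 1)))


def test_mixture_of_identical_sequences_collapses(rng, three_flat_events):
    seq = sequential_sequence(3)
    x = rng.normal(0.5, 1.0, size=(9, 3))
    noise = ss.NoiseModel.unit(3)
    single = ss.SubtypeMixtureModel(three_flat_events, [seq],
                                    np.array([1.0]), noise)
    double = ss.SubtypeMixtureModel(three_flat_events, [seq, seq],
                                    np.array([0.5, 0.5]), noise)
    ll1, _ = ss.mixture_log_likelihood(make_dataset(x), single)
    ll2, _ = ss.mixture_log_likelihood(make_dataset(x), double)
    assert ll2 == pytest.approx(ll1, abs=1e-9)


def test_separated_subtypes_give_confident_posteriors():
    """A subject simulated deep in one subtype is attributed to it."""
    es = ss.ZScoreEventSet.uniform(["a", "b", "c"], z=(1.0,), z_max=2.0)
    s1 = ss.SubtypeSequence([0, 1, 2])
    s2 = ss.SubtypeSequence([2, 1, 0])
    noise = ss.NoiseModel(np.full(3, 0.1))
    model = ss.SubtypeMixtureModel(es, [s1, s2], np.array([0.5, 0.5]), noise)
    t = 0.45   # a has completed, b mid-rise, c not started (subtype 1)
    x = [[ss.trajectory_value(es, s1, i, t) for i in range(3)]]
    _, post = ss.mixture_log_likelihood(make_dataset(x, ["a", "b", "c"]),
                                        model)
    assert post[0, 0] > 0.99


def test_mixture_invariant_to_subtype_relabelling(rng, three_flat_events):
    x = rng.normal(0.5, 1.0, size=(9, 3))
    noise = ss.NoiseModel.unit(3)
    s1 = ss.SubtypeSequence([0, 1, 2])
    s2 = ss.SubtypeSequence([2, 0, 1])
    m = ss.SubtypeMixtureModel(three_flat_events, [s1, s2],
                               np.array([0.3, 0.7]), noise)
    m_perm = ss.SubtypeMixtureModel(three_flat_events, [s2, s1],
                                    np.array([0.7, 0.3]), noise)
    ll, _ = ss.mixture_log_likelihood(make_dataset(x), m)
    ll_perm, _ = ss.mixture_log_likelihood(make_dataset(x), m_perm)
    assert ll == pytest.approx(ll_perm, abs=1e-9)


def test_model_validation_errors(three_flat_events):
    seq = sequential_sequence(3)
    noise = ss.NoiseModel.unit(3)
    with pytest.raises(ValueError):
        ss.SubtypeMixtureModel(three_flat_events, [seq, seq],
                               np.array([0.6, 0.6]), noise)
    with pytest.raises(ValueError):
        ss.ZScoreEventSet(["a"], [np.array([2.0, 1.0])], np.array([3.0]))
    with pytest.raises(ValueError):
        ss.ZScoreEventSet(["a"], [np.array([1.0, 2.0])], np.array([2.0]))


# ---------------------------------------------------------------------------
# Admissible sequences
# ---------------------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_random_admissible_sequences_are_admissible(seed):
    rng = np.random.default_rng(seed)
    es = ss.ZScoreEventSet.uniform(["a", "b"], z=(1.0, 2.0, 3.0), z_max=5.0)
    seq = ss.random_admissible_sequence(es, rng)
    assert ss.is_admissible(seq.order, es)


def test_random_admissible_draw_is_uniform():
    """With 2 biomarkers x 2 z-levels there are 4!/(2!2!) = 6 admissible
    orders; the sampler should hit them about equally often."""
    es = ss.ZScoreEventSet.uniform(["a", "b"], z=(1.0, 2.0), z_max=3.0)
    all_orders = ss.enumerate_admissible_sequences(es)
    assert len(all_orders) == 6
    rng = np.random.default_rng(5)
    counts = {tuple(o): 0 for o in all_orders}
    n = 6000
    for _ in range(n):
        counts[tuple(ss.random_admissible_sequence(es, rng).order)] += 1
    freqs = np.array(list(counts.values())) / n
    assert np.all(np.abs(freqs - 1 / 6) < 0.03)


def test_enumeration_respects_within_biomarker_order(single_biomarker_events):
    orders = ss.enumerate_admissible_sequences(single_biomarker_events)
    assert len(orders) == 1          # z=1 must precede z=2
    np.testing.assert_array_equal(orders[0], [0, 1])


# ---------------------------------------------------------------------------
# Batched evaluation consistency
# ---------------------------------------------------------------------------

def test_batched_and_single_likelihoods_agree(rng):
    es = ss.ZScoreEventSet.uniform(["a", "b"], z=(1.0, 2.0), z_max=3.0)
    data = make_dataset(rng.normal(1.0, 1.0, size=(7, 2)), ["a", "b"])
    eng = LikelihoodEngine(data, es, ss.NoiseModel.unit(2))
    orders = np.stack([o for o in ss.enumerate_admissible_sequences(es)])
    batch = eng.subject_log_likelihood_batch(orders)
    for b, order in enumerate(orders):
        np.testing.assert_allclose(batch[b],
                                   eng.subject_log_likelihood(order),
                                   atol=1e-12)
    stage_batch = eng.stage_log_likelihood_batch(orders)
    np.testing.assert_allclose(stage_batch[2],
                               eng.stage_log_likelihood(orders[2]),
                               atol=1e-12)
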