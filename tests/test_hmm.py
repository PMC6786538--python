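"""Unit and oracle tests for the two-state Gaussian HMM.

The independent oracle throughout is exhaustive enumeration over all
2^(T-1) hidden-state paths: the forward log-likelihood must equal the
log-sum over path joint probabilities, and the Viterbi path must equal the
enumeration argmax.  hmmlearn provides a second, external cross-check.
"""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from hmmselect import (
    DeltaTensor,
    EMConfig,
    HMMParameters,
    ShapeError,
    decode_tensor,
    em_fit,
    emission_logdensity,
    forward_backward,
    simulate_dataset,
    viterbi_decode,
)
from hmmselect.simulator import SimulationConfig

from conftest import random_parameters


def enumerate_paths(params: HMMParameters, seq: np.ndarray):
    """Joint log-probability of every hidden path (brute force)."""
    length = seq.shape[0]
    log_pi = np.log(params.initial)
    log_a = np.log(params.transition)
    log_b = np.stack(
        [
            np.atleast_1d(
                multivariate_normal.logpdf(seq, params.means[k], params.covariances[k])
            )
            for k in range(2)
        ],
        axis=1,
    ).reshape(length, 2)
    paths = list(itertools.product((0, 1), repeat=length))
    joint = []
    for path in paths:
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, length):
            lp += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
        joint.append(lp)
    return paths, np.array(joint)


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------


def test_emission_standard_normal_closed_form():
    params = HMMParameters(
        [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[0.0], [0.0]], [[[1.0]], [[4.0]]]
    )
    assert emission_logdensity(params, [0.0], "N") == pytest.approx(
        -0.5 * np.log(2 * np.pi)
    )


def test_emission_identical_states_are_symmetric():
    params = HMMParameters(
        [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.1, -0.2], [0.1, -0.2]],
        [np.eye(2) * 0.7, np.eye(2) * 0.7],
    )
    obs = [1.3, -2.1]
    assert emission_logdensity(params, obs, "N") == emission_logdensity(
        params, obs, "C"
    )


def test_emission_diagonal_covariance_sums_univariate_terms():
    variances = np.array([0.5, 2.0])
    means = np.array([0.3, -0.4])
    params = HMMParameters(
        [0.5, 0.5],
        [[0.9, 0.1], [0.1, 0.9]],
        [means, means],
        [np.diag(variances), np.diag(variances)],
    )
    obs = np.array([1.0, 0.5])
    expected = sum(
        multivariate_normal.logpdf(obs[i], means[i], variances[i]) for i in range(2)
    )
    assert emission_logdensity(params, obs, "C") == pytest.approx(expected, abs=1e-12)


def test_emission_dimension_mismatch_raises():
    params = HMMParameters(
        [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[0.0], [0.0]], [[[1.0]], [[4.0]]]
    )
    with pytest.raises(ShapeError):
        emission_logdensity(params, [0.0, 1.0], "N")


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def test_forward_backward_length_one_posterior_is_normalized_prior_times_emission():
    params = HMMParameters(
        [0.3, 0.7], [[0.9, 0.1], [0.2, 0.8]], [[0.0], [0.0]], [[[0.04]], [[1.0]]]
    )
    obs = np.array([[0.5]])
    result = forward_backward(params, obs)
    weights = np.array(
        [
            params.initial[k]
            * np.exp(emission_logdensity(params, obs[0], "NC"[k]))
            for k in range(2)
        ]
    )
    np.testing.assert_allclose(result.gamma[0], weights / weights.sum(), atol=1e-12)
    assert result.xi.shape == (0, 2, 2)


def test_forward_backward_symmetric_model_gives_half_half():
    params = HMMParameters(
        [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.0], [0.0]], [[[1.0]], [[1.0]]]
    )
    result = forward_backward(params, np.array([[0.3], [-1.2], [2.0]]))
    np.testing.assert_allclose(result.gamma, 0.5, atol=1e-12)


@pytest.mark.parametrize("length,r", [(1, 1), (2, 2), (3, 1), (5, 3), (8, 2), (10, 1)])
def test_forward_likelihood_matches_path_enumeration(length, r):
    rng = np.random.default_rng(100 * length + r)
    params = random_parameters(rng, r)
    seq = rng.normal(0.0, 1.5, size=(length, r))
    _, joint = enumerate_paths(params, seq)
    result = forward_backward(params, seq)
    assert result.log_likelihood == pytest.approx(logsumexp(joint), abs=1e-8)
    np.testing.assert_allclose(result.gamma.sum(axis=1), 1.0, atol=1e-10)
    if length > 1:
        np.testing.assert_allclose(result.xi.sum(axis=(1, 2)), 1.0, atol=1e-10)


def test_forward_backward_empty_sequence_rejected():
    params = HMMParameters(
        [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[0.0], [0.0]], [[[1.0]], [[4.0]]]
    )
    with pytest.raises(ShapeError):
        forward_backward(params, np.empty((0, 1)))


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("length,r", [(1, 1), (2, 3), (4, 2), (6, 1), (10, 2)])
def test_viterbi_matches_enumeration_argmax(length, r):
    rng = np.random.default_rng(31 * length + r)
    for _ in range(5):
        params = random_parameters(rng, r)
        seq = rng.normal(0.0, 1.5, size=(length, r))
        paths, joint = enumerate_paths(params, seq)
        best = paths[int(np.argmax(joint))]
        decoded = viterbi_decode(params, seq)
        assert decoded.states == "".join("NC"[k] for k in best)
        assert decoded.log_probability == pytest.approx(joint.max(), abs=1e-8)


def test_viterbi_exact_tie_prefers_null_state():
    # identical emissions and fully symmetric chain: every path ties
    params = HMMParameters(
        [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.0], [0.0]], [[[1.0]], [[1.0]]]
    )
    decoded = viterbi_decode(params, np.array([[0.2], [-0.4], [1.0], [0.0]]))
    assert decoded.states == "NNNN"


def test_viterbi_large_observation_decodes_change():
    params = HMMParameters(
        [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.0], [0.0]], [[[0.04]], [[1.0]]]
    )
    decoded = viterbi_decode(params, np.array([[0.01], [5.0], [0.01]]))
    assert decoded.states == "NCN"


def test_decoding_is_independent_of_other_sequences(small_tensors):
    from hmmselect import delta_transform

    deltas = delta_transform(small_tensors[0])
    params = HMMParameters(
        [0.5, 0.5],
        [[0.9, 0.1], [0.1, 0.9]],
        np.zeros((2, 2)),
        [np.eye(2) * 0.04, np.eye(2) * 1.0],
    )
    batch = decode_tensor(params, deltas)
    for g, path in enumerate(batch):
        single = viterbi_decode(
            params, deltas.sequences()[g], path.feature_id, path.condition
        )
        assert single.states == path.states
        assert single.log_probability == pytest.approx(path.log_probability)


def test_hmmlearn_cross_check_loglik_and_viterbi():
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(5)
    for r, length in [(1, 4), (2, 6), (3, 5)]:
        params = random_parameters(rng, r)
        seq = rng.normal(0.0, 1.0, size=(length, r))
        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="full", init_params="")
        model.startprob_ = params.initial
        model.transmat_ = params.transition
        model.means_ = params.means
        model.covars_ = params.covariances
        ref_ll, ref_path = model.decode(seq, algorithm="viterbi")
        assert forward_backward(params, seq).log_likelihood == pytest.approx(
            model.score(seq), abs=1e-8
        )
        decoded = viterbi_decode(params, seq)
        assert decoded.states == "".join("NC"[k] for k in ref_path)
        assert decoded.log_probability == pytest.approx(ref_ll, abs=1e-8)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _random_delta_tensor(rng, g=20, r=2, length=4, condition="case"):
    deltas = rng.normal(0.0, 1.0, size=(g, r, length))
    ids = tuple(f"g{i}" for i in range(g))
    return DeltaTensor(condition, deltas, ids)


@pytest.mark.parametrize("seed", range(8))
def test_em_loglik_monotone_and_parameters_on_simplex(seed):
    rng = np.random.default_rng(seed)
    tensor = _random_delta_tensor(rng)
    report = em_fit([tensor], EMConfig(max_iter=60, restarts=1, seed=seed))
    trace = np.array(report.log_likelihood_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))
    params = report.parameters
    assert params.initial.sum() == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(params.transition.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(params.initial >= 0) and np.all(params.transition >= 0)


def test_em_recovers_state_dispersions_from_simulation():
    """Fitting simulator output recovers the generating per-state sds.

    The generated per-replicate deltas have marginal variance
    sd_state^2 + 2*noise^2, which is what the fitted emission covariance
    estimates; the comparison is against the configured (1.0, 0.2) at
    that tolerance.
    """
    cfg = SimulationConfig(n_features=3000, seed=11)
    tensors, _ = simulate_dataset(cfg)
    from hmmselect import delta_transform, shuffle_features

    deltas = [delta_transform(t) for t in tensors]
    shuffled, _ = shuffle_features(deltas, seed=11)
    report = em_fit(shuffled, EMConfig(seed=11))
    sds = np.sqrt(
        [np.mean(np.diag(report.parameters.covariances[k])) for k in range(2)]
    )
    assert abs(sds[0] - cfg.sd_nochange) < 0.05
    assert abs(sds[1] - cfg.sd_change) < 0.05
    # zero-mean constraint holds exactly
    np.testing.assert_array_equal(report.parameters.means, 0.0)
    # change state is the larger-dispersion one by the labeling convention
    assert np.trace(report.parameters.covariances[1]) >= np.trace(
        report.parameters.covariances[0]
    )


def test_em_is_deterministic_given_seed():
    rng = np.random.default_rng(3)
    tensor = _random_delta_tensor(rng, g=30)
    a = em_fit([tensor], EMConfig(seed=99))
    b = em_fit([tensor], EMConfig(seed=99))
    assert a.log_likelihood_trace == b.log_likelihood_trace
    np.testing.assert_array_equal(a.parameters.transition, b.parameters.transition)
    np.testing.assert_array_equal(a.parameters.covariances, b.parameters.covariances)


def test_em_refuses_fewer_than_two_sequences():
    tensor = DeltaTensor("case", np.zeros((1, 2, 3)), ("g0",))
    with pytest.raises(ShapeError):
        em_fit([tensor])


def test_em_all_zero_observations_hits_variance_floor_with_warning():
    tensor = DeltaTensor("case", np.zeros((10, 1, 3)), tuple(f"g{i}" for i in range(10)))
    with pytest.warns(UserWarning, match="variance floor"):
        report = em_fit([tensor], EMConfig(restarts=1, max_iter=10))
    assert np.all(np.linalg.eigvalsh(report.parameters.covariances[0]) >= 1e-9)


def test_parameters_json_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    params = random_parameters(rng, 3)
    path = tmp_path / "model.json"
    params.save(path)
    loaded = HMMParameters.load(path)
    np.testing.assert_allclose(loaded.initial, params.initial)
    np.testing.assert_allclose(loaded.transition, params.transition)
    np.testing.assert_allclose(loaded.means, params.means)
    np.testing.assert_allclose(loaded.covariances, params.covariances)
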