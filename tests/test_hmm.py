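"""Bakis HMM: topology, forward oracle, EM behavior, sampling."""

import itertools

import numpy as np
import pytest

from ffrbio.hmm import (
    BakisHMM,
    bakis_transition_mask,
    init_bakis,
    log_probability,
    sample_sequence,
    train_baum_welch,
)


def brute_force_log_probability(model, seqs):
    """Exhaustive sum over all hidden state paths (oracle).

    Vectorized over paths and sequences of a common length.
    """
    pi, A, E = model.startprob_, model.transmat_, model.emissionprob_
    S = model.n_states
    seqs = np.atleast_2d(np.asarray(seqs))
    L = seqs.shape[1]
    paths = np.array(list(itertools.product(range(S), repeat=L)))  # (P, L)
    prior = pi[paths[:, 0]]
    for t in range(1, L):
        prior = prior * A[paths[:, t - 1], paths[:, t]]
    probs = np.ones((paths.shape[0], seqs.shape[0]))
    for t in range(L):
        probs *= E[paths[:, t]][:, seqs[:, t]]
    return np.log((prior[:, None] * probs).sum(axis=0))


def make_planted(seed, n_states=3, n_symbols=8, alpha=0.3):
    """Planted Bakis model with well-separated (sparse) emission rows."""
    rng = np.random.default_rng(seed)
    mask = bakis_transition_mask(n_states).astype(float)
    A = mask * rng.uniform(0.5, 1.5, mask.shape)
    A /= A.sum(axis=1, keepdims=True)
    E = rng.dirichlet(np.full(n_symbols, alpha), size=n_states)
    E = np.maximum(E, 1e-6)
    E /= E.sum(axis=1, keepdims=True)
    pi = np.zeros(n_states)
    pi[0] = 1.0
    return BakisHMM.from_params(pi, A, E)


@pytest.fixture(scope="module")
def small_model():
    return init_bakis(n_states=3, n_symbols=4, seed=11)


class TestTopology:
    def test_allowed_support_steps_of_one_and_two(self, small_model):
        mask = bakis_transition_mask(3)
        expected = {(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)}
        assert {tuple(ij) for ij in np.argwhere(mask)} == expected
        assert np.all(small_model.transmat_[~mask] == 0.0)

    def test_rows_stochastic(self, small_model):
        assert np.allclose(small_model.transmat_.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(small_model.emissionprob_.sum(axis=1), 1.0, atol=1e-9)
        assert small_model.startprob_.sum() == pytest.approx(1.0)
        assert small_model.startprob_[0] == pytest.approx(1.0)

    def test_invalid_topology_errors(self):
        with pytest.raises(ValueError):
            init_bakis(n_states=0)
        with pytest.raises(ValueError):
            init_bakis(n_states=3, n_symbols=1)


class TestForward:
    def test_matches_exhaustive_path_enumeration(self, small_model):
        """Forward log-probabilities equal the brute-force path sum, <=1e-10."""
        rng = np.random.default_rng(0)
        for L in range(1, 7):
            if L <= 4:
                seqs = np.array(list(itertools.product(range(4), repeat=L)))
            else:
                seqs = rng.integers(0, 4, size=(60, L))
            ours = small_model.score_sequences(seqs)
            oracle = brute_force_log_probability(small_model, seqs)
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_matches_hmmlearn_forward(self, small_model):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = small_model.startprob_
        ref.transmat_ = small_model.transmat_
        ref.emissionprob_ = small_model.emissionprob_
        ref.n_features = 4
        rng = np.random.default_rng(1)
        seqs = rng.integers(0, 4, size=(20, 10))
        ours = small_model.score_sequences(seqs)
        theirs = np.array([ref.score(s.reshape(-1, 1)) for s in seqs])
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_length_one_closed_form(self, small_model):
        for o in range(4):
            expected = np.log(
                np.sum(small_model.startprob_ * small_model.emissionprob_[:, o])
            )
            assert log_probability(small_model, np.array([o])) == pytest.approx(
                expected, abs=1e-12
            )

    def test_deterministic_degenerate_model_scores_zero(self):
        model = BakisHMM.from_params([1.0], [[1.0]], [[1.0, 0.0]])
        assert log_probability(model, np.array([0, 0, 0])) == pytest.approx(0.0)

    def test_out_of_range_symbol_errors(self, small_model):
        with pytest.raises(ValueError, match="symbols"):
            small_model.score_sequences(np.array([[0, 4]]))

    def test_empty_sequence_errors(self, small_model):
        with pytest.raises(ValueError):
            small_model.score_sequences(np.zeros((1, 0), dtype=int))


@pytest.fixture(scope="module")
def training_seqs():
    planted = make_planted(3, n_symbols=6)
    return np.stack([planted.sample(30, random_state=s) for s in range(100)])


class TestBaumWelch:
    def test_loglik_history_monotone(self, training_seqs):
        model = BakisHMM(
            n_states=3, n_symbols=6, n_restarts=1, n_iter=40, tol=0.0, random_state=5
        ).fit(training_seqs)
        diffs = np.diff(model.loglik_history_)
        assert np.all(diffs >= -1e-8)

    def test_zero_mask_preserved_after_training(self, training_seqs):
        model = BakisHMM(n_states=3, n_symbols=6, n_restarts=2, random_state=6).fit(
            training_seqs
        )
        mask = bakis_transition_mask(3)
        assert np.all(model.transmat_[~mask] == 0.0)
        assert np.allclose(model.transmat_.sum(axis=1), 1.0, atol=1e-9)

    def test_training_beats_random_initialization_on_heldout(self):
        planted = make_planted(7)
        train = np.stack([planted.sample(40, random_state=s) for s in range(80)])
        held = np.stack([planted.sample(40, random_state=1000 + s) for s in range(30)])
        random_init = init_bakis(n_states=3, n_symbols=8, seed=99)
        trained = BakisHMM(
            n_states=3, n_symbols=8, n_restarts=3, random_state=8
        ).fit(train)
        assert trained.score(held) > random_init.score(held)

    def test_no_symbol_has_zero_probability_after_flooring(self, training_seqs):
        model = BakisHMM(n_states=3, n_symbols=6, random_state=9).fit(training_seqs)
        assert np.all(model.emissionprob_ > 0)

    def test_out_of_range_symbol_errors(self):
        with pytest.raises(ValueError, match="symbols"):
            BakisHMM(n_states=3, n_symbols=150).fit(np.full((2, 5), 150))

    def test_empty_sequence_list_errors(self):
        with pytest.raises(ValueError):
            BakisHMM().fit([])

    def test_parameter_recovery_beats_mismatched_model(self):
        """Trained models out-predict a mismatched planted model on held-out
        data in >=19/20 seeded replicates."""
        wins = 0
        for rep in range(20):
            planted = make_planted(100 + rep, n_symbols=10)
            mismatched = make_planted(500 + rep, n_symbols=10)
            train = np.stack(
                [planted.sample(47, random_state=3 * rep * 1000 + s) for s in range(60)]
            )
            held = np.stack(
                [
                    planted.sample(47, random_state=7_000_000 + rep * 1000 + s)
                    for s in range(20)
                ]
            )
            trained = BakisHMM(
                n_states=3, n_symbols=10, n_restarts=2, n_iter=50,
                random_state=rep,
            ).fit(train)
            if trained.score(held) > mismatched.score(held):
                wins += 1
        assert wins >= 19

    def test_wrapper_roundtrip(self, training_seqs):
        model = init_bakis(n_states=3, n_symbols=6, seed=1)
        train_baum_welch(model, training_seqs, tol=1e-4, max_iter=30)
        clone = BakisHMM.from_json(model.to_json())
        seq = training_seqs[0]
        assert clone.score_sequences([seq])[0] == pytest.approx(
            model.score_sequences([seq])[0]
        )


class TestSampling:
    def test_same_seed_same_sequence(self, small_model):
        a = sample_sequence(small_model, 20, seed=4)
        b = sample_sequence(small_model, 20, seed=4)
        assert np.array_equal(a.symbols, b.symbols)

    def test_deterministic_chain_produces_certain_sequence(self):
        model = BakisHMM.from_params(
            [1.0, 0.0],
            [[0.0, 1.0], [0.0, 1.0]],
            [[1.0, 0.0], [0.0, 1.0]],
        )
        assert model.sample(4, random_state=0).tolist() == [0, 1, 1, 1]

    def test_empirical_frequencies_match_emission_row(self):
        model = BakisHMM.from_params([1.0], [[1.0]], [[0.2, 0.5, 0.3]])
        draws = model.sample(10000, random_state=2)
        freqs = np.bincount(draws, minlength=3) / draws.size
        assert np.allclose(freqs, [0.2, 0.5, 0.3], atol=0.02)

    def test_invalid_length_errors(self, small_model):
        with pytest.raises(ValueError):
            small_model.sample(0)
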