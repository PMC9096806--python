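"""Discrete-emission Bakis (left-to-right) hidden Markov model.

The model is a chain of ``n_states`` hidden states connected feedforward in
steps of one and two (plus self-loops): ``transmat[i, j]`` may be nonzero
only for ``j`` in ``{i, i+1, i+2}``.  Emissions are categorical over the
vector-quantization symbols.  Training is Baum-Welch (EM) with the scaled
forward-backward recursions, vectorized across equal-length sequences;
similarity scoring is the exact forward-algorithm log-probability.

The EM implementation preserves the Bakis zero mask exactly (a transition
that starts at zero has a zero expected count, so it stays zero), and its
per-iteration total log-likelihood is non-decreasing.  After training, a
small emission floor is mixed in and rows renormalized so that a held-out
sequence containing a symbol unseen in training scores finitely instead of
-inf.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import EmissionSequence

__all__ = [
    "BakisHMM",
    "bakis_transition_mask",
    "init_bakis",
    "train_baum_welch",
    "log_probability",
    "sample_sequence",
]


def bakis_transition_mask(n_states: int) -> np.ndarray:
    """Boolean mask of allowed transitions: self, +1 and +2 steps."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    i = np.arange(n_states)[:, None]
    j = np.arange(n_states)[None, :]
    return (j >= i) & (j <= i + 2)


def _as_batches(X) -> list[np.ndarray]:
    """Normalize input to a list of 2-D int batches of equal-length rows."""
    if isinstance(X, EmissionSequence):
        X = [X.symbols]
    elif isinstance(X, np.ndarray) and X.ndim == 2:
        X = [np.asarray(row) for row in X]
    elif isinstance(X, np.ndarray) and X.ndim == 1:
        X = [X]
    seqs = []
    for s in X:
        s = s.symbols if isinstance(s, EmissionSequence) else np.asarray(s)
        s = np.asarray(s, dtype=np.int64)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("each emission sequence must be a nonempty 1-D array")
        seqs.append(s)
    if not seqs:
        raise ValueError("at least one emission sequence is required")
    batches: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        batches.setdefault(s.size, []).append(s)
    return [np.stack(group) for group in batches.values()]


class BakisHMM(BaseEstimator):
    """Feedforward discrete-emission HMM with Baum-Welch training.

    Parameters
    ----------
    n_states, n_symbols : int
        Topology (default 3 states) and emission alphabet size (default
        150, the codebook size).
    n_iter, tol : int, float
        EM stops when the relative total log-likelihood improvement falls
        below ``tol`` or after ``n_iter`` iterations.
    n_restarts : int
        Seeded re-initializations; the restart with the best final
        likelihood is kept.
    emission_floor : float
        Probability mixed into every emission cell after training so no
        symbol scores -inf at test time.
    start_on_first : bool
        Put all initial probability on the first state (left-to-right
        convention, default) instead of a uniform start.

    Attributes
    ----------
    startprob_, transmat_, emissionprob_ : ndarray
        Fitted probability tables.
    loglik_history_ : list of float
        Per-iteration total training log-likelihood of the winning restart
        (computed before the emission floor is applied).
    """

    def __init__(
        self,
        n_states: int = 3,
        n_symbols: int = 150,
        n_iter: int = 100,
        tol: float = 1e-4,
        n_restarts: int = 5,
        emission_floor: float = 1e-6,
        init_jitter: float = 0.1,
        start_on_first: bool = True,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.n_iter = n_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.emission_floor = emission_floor
        self.init_jitter = init_jitter
        self.start_on_first = start_on_first
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # initialization
    # ------------------------------------------------------------------ #

    def _validate_topology(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_symbols < 2:
            raise ValueError("n_symbols must be >= 2")

    def _init_params(self, rng: np.random.Generator, symbol_freq=None):
        mask = bakis_transition_mask(self.n_states)
        A = np.where(mask, 1.0 + self.init_jitter * rng.uniform(-1, 1, mask.shape), 0.0)
        A /= A.sum(axis=1, keepdims=True)
        if self.start_on_first:
            pi = np.zeros(self.n_states)
            pi[0] = 1.0
        else:
            pi = np.full(self.n_states, 1.0 / self.n_states)
        if symbol_freq is None:
            E = 1.0 + self.init_jitter * rng.uniform(-1, 1, (self.n_states, self.n_symbols))
        else:
            E = (symbol_freq + 1.0 / self.n_symbols) * (
                1.0 + 0.5 * rng.uniform(-1, 1, (self.n_states, self.n_symbols))
            )
        E /= E.sum(axis=1, keepdims=True)
        return pi, A, E

    def initialize(self, random_state: int | None = None) -> "BakisHMM":
        """Set seeded initial parameters without training (usable as-is)."""
        self._validate_topology()
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        self.startprob_, self.transmat_, self.emissionprob_ = self._init_params(rng)
        self.loglik_history_ = []
        return self

    @classmethod
    def from_params(cls, startprob, transmat, emissionprob, **kwargs) -> "BakisHMM":
        """Build a scorable model from explicit probability tables."""
        startprob = np.asarray(startprob, dtype=float)
        transmat = np.asarray(transmat, dtype=float)
        emissionprob = np.asarray(emissionprob, dtype=float)
        n_states, n_symbols = emissionprob.shape
        model = cls(n_states=n_states, n_symbols=n_symbols, **kwargs)
        for name, arr, axis in (
            ("startprob", startprob, None),
            ("transmat", transmat, 1),
            ("emissionprob", emissionprob, 1),
        ):
            s = arr.sum() if axis is None else arr.sum(axis=axis)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        model.startprob_ = startprob
        model.transmat_ = transmat
        model.emissionprob_ = emissionprob
        model.loglik_history_ = []
        return model

    # ------------------------------------------------------------------ #
    # forward / backward
    # ------------------------------------------------------------------ #

    def _check_symbols(self, batch: np.ndarray) -> None:
        if batch.max() >= self.n_symbols or batch.min() < 0:
            raise ValueError(
                f"emission symbols must lie in [0, {self.n_symbols}); "
                f"found range [{batch.min()}, {batch.max()}]"
            )

    @staticmethod
    def _forward(pi, A, B):
        """Scaled forward pass.

        ``B`` has shape (S, N, T).  Returns per-sequence log-likelihoods,
        the scaled alpha array (T, S, N) and scale factors (T, N).
        """
        S, N, T = B.shape
        alpha = np.empty((T, S, N))
        c = np.empty((T, N))
        a = pi[:, None] * B[:, :, 0]
        c[0] = a.sum(axis=0)
        alpha[0] = a / c[0]
        for t in range(1, T):
            a = (A.T @ alpha[t - 1]) * B[:, :, t]
            c[t] = a.sum(axis=0)
            alpha[t] = a / c[t]
        return np.log(c).sum(axis=0), alpha, c

    def score_sequences(self, X) -> np.ndarray:
        """Forward-algorithm log P(sequence | model), one value per sequence."""
        check_is_fitted(self, "transmat_")
        lls = []
        for batch in _as_batches(X):
            self._check_symbols(batch)
            B = self.emissionprob_[:, batch]  # (S, N, T)
            ll, _, _ = self._forward(self.startprob_, self.transmat_, B)
            lls.append(ll)
        return np.concatenate(lls)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of a set of sequences."""
        return float(self.score_sequences(X).sum())

    # ------------------------------------------------------------------ #
    # Baum-Welch
    # ------------------------------------------------------------------ #

    def _em_step(self, pi, A, E, batches):
        """One EM iteration over all batches.

        Returns the total log-likelihood under the *current* parameters
        and the updated (pi, A, E).
        """
        S, K = E.shape
        total_ll = 0.0
        pi_num = np.zeros(S)
        trans_num = np.zeros((S, S))
        emis_num = np.zeros((S, K))
        n_seq_total = 0
        for batch in batches:
            N, T = batch.shape
            n_seq_total += N
            B = E[:, batch]  # (S, N, T)
            ll, alpha, c = self._forward(pi, A, B)
            total_ll += float(ll.sum())
            # scaled backward
            beta = np.empty_like(alpha)
            beta[T - 1] = 1.0
            for t in range(T - 2, -1, -1):
                bb = B[:, :, t + 1] * beta[t + 1] / c[t + 1]
                beta[t] = A @ bb
                trans_num += np.einsum("in,ij,jn->ij", alpha[t], A, bb)
            gamma = alpha * beta  # (T, S, N), rows sum to 1 over S
            pi_num += gamma[0].sum(axis=1)
            # emission counts: gamma is (T, S, N); symbols are (N, T)
            gs = np.transpose(gamma, (1, 0, 2)).reshape(S, T * N)
            sym = batch.T.reshape(T * N)
            for s in range(S):
                emis_num[s] += np.bincount(sym, weights=gs[s], minlength=K)
        new_pi = pi_num / n_seq_total
        row = trans_num.sum(axis=1, keepdims=True)
        new_A = np.where(row > 0, trans_num / np.where(row == 0, 1.0, row), A)
        erow = emis_num.sum(axis=1, keepdims=True)
        new_E = np.where(erow > 0, emis_num / np.where(erow == 0, 1.0, erow), E)
        return total_ll, new_pi, new_A, new_E

    def fit(self, X, y=None) -> "BakisHMM":
        """Baum-Welch training with multiple seeded restarts."""
        self._validate_topology()
        batches = _as_batches(X)
        for batch in batches:
            self._check_symbols(batch)
        counts = np.zeros(self.n_symbols)
        total = 0
        for batch in batches:
            counts += np.bincount(batch.reshape(-1), minlength=self.n_symbols)
            total += batch.size
        symbol_freq = counts / total

        root = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        best = None
        for child in root.spawn(max(1, self.n_restarts)):
            rng = np.random.default_rng(child)
            pi, A, E = self._init_params(rng, symbol_freq=symbol_freq)
            history = []
            prev = -np.inf
            for _ in range(self.n_iter):
                ll, pi_new, A_new, E_new = self._em_step(pi, A, E, batches)
                history.append(ll)
                if np.isfinite(prev) and ll - prev < self.tol * abs(prev):
                    pi, A, E = pi_new, A_new, E_new
                    break
                pi, A, E = pi_new, A_new, E_new
                prev = ll
            final_ll = history[-1]
            if best is None or final_ll > best[0]:
                best = (final_ll, pi, A, E, history)

        _, pi, A, E, history = best
        if self.emission_floor > 0:
            E = E + self.emission_floor
            E /= E.sum(axis=1, keepdims=True)
        self.startprob_, self.transmat_, self.emissionprob_ = pi, A, E
        self.loglik_history_ = history
        self.n_iter_ = len(history)
        self.converged_ = len(history) < self.n_iter
        return self

    # ------------------------------------------------------------------ #
    # sampling and (de)serialization
    # ------------------------------------------------------------------ #

    def sample(self, length: int, random_state: int | None = None) -> np.ndarray:
        """Ancestral sampling of one emission sequence."""
        check_is_fitted(self, "transmat_")
        if length < 1:
            raise ValueError("length must be >= 1")
        rng = np.random.default_rng(random_state)
        symbols = np.empty(length, dtype=np.int64)
        state = rng.choice(self.n_states, p=self.startprob_)
        for t in range(length):
            symbols[t] = rng.choice(self.n_symbols, p=self.emissionprob_[state])
            state = rng.choice(self.n_states, p=self.transmat_[state])
        return symbols

    def to_json(self) -> str:
        check_is_fitted(self, "transmat_")
        return json.dumps(
            {
                "n_states": self.n_states,
                "n_symbols": self.n_symbols,
                "startprob": self.startprob_.tolist(),
                "transmat": self.transmat_.tolist(),
                "emissionprob": self.emissionprob_.tolist(),
                "random_state": self.random_state,
                "loglik_history": [float(v) for v in self.loglik_history_],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "BakisHMM":
        d = json.loads(payload)
        model = cls.from_params(
            d["startprob"], d["transmat"], d["emissionprob"]
        )
        model.random_state = d.get("random_state")
        model.loglik_history_ = d.get("loglik_history", [])
        return model


# ---------------------------------------------------------------------- #
# thin functional wrappers
# ---------------------------------------------------------------------- #


def init_bakis(n_states: int = 3, n_symbols: int = 150, seed: int | None = None) -> BakisHMM:
    """A freshly initialized (untrained but scorable) Bakis model."""
    return BakisHMM(n_states=n_states, n_symbols=n_symbols, random_state=seed).initialize()


def train_baum_welch(
    model: BakisHMM, sequences, tol: float | None = None, max_iter: int | None = None
) -> BakisHMM:
    """Train ``model`` in place on a list/array of emission sequences."""
    if tol is not None:
        model.tol = tol
    if max_iter is not None:
        model.n_iter = max_iter
    return model.fit(sequences)


def log_probability(model: BakisHMM, seq) -> float:
    """Forward log-probability of a single emission sequence."""
    return float(model.score_sequences([seq])[0])


def sample_sequence(model: BakisHMM, length: int, seed: int | None = None) -> EmissionSequence:
    return EmissionSequence(symbols=model.sample(length, random_state=seed))
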