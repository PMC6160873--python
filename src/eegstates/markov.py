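"""Markov models of state-symbol sequences and the model-distance test.

Each experimental condition yields a trials x T matrix of state symbols in
1..Q.  A first-order Markov chain (initial probabilities ``pi`` and a
row-stochastic transition matrix ``Tm``) is the maximum-likelihood
description of such a matrix, and with an identity emission matrix the
Baum-Welch EM fixed point coincides with the closed-form counting MLE
implemented here: ``pi_i`` is the fraction of trials starting in state i
and ``Tm[i, j]`` the fraction of transitions out of i that go to j.

Conditions are compared through the Rabiner model distance

    D(M1, M2) = [log P(S2 | M1) - log P(S2 | M2)] / (T * n_trials_2)

symmetrized as the average of D(M1, M2) and D(M2, M1).  When both models
are the MLEs of their own sequences, D_sym <= 0 by likelihood maximality,
and more negative values mean more distinguishable conditions.  Zero
probabilities are floored at machine epsilon before taking logs so the
log-likelihood stays finite.  Significance is assessed against the lower
tail of a permutation null built by reassigning pooled trials to two
pseudo-conditions of the original sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "MarkovModel",
    "MarkovChain",
    "estimate_markov",
    "sequence_loglik",
    "model_distance",
    "permutation_test",
    "sample_sequences",
]

#: default floor replacing zero probabilities in log-likelihoods (eps)
PROB_FLOOR = 2.2204e-16


@dataclass
class MarkovModel:
    """Initial probabilities and transition matrix over Q states."""

    pi: np.ndarray
    Tm: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.Tm = np.asarray(self.Tm, dtype=float)
        Q = self.pi.shape[0]
        if self.Tm.shape != (Q, Q):
            raise ValueError("Tm must be Q x Q")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector")
        if np.any(self.Tm < 0) or np.any(np.abs(self.Tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("Tm rows must be probability vectors")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]


def _check_sequences(S: np.ndarray, Q: int) -> np.ndarray:
    S = np.asarray(S)
    if S.ndim == 1:
        S = S[None, :]
    if S.shape[1] < 2:
        raise ValueError("sequences must have at least 2 symbols (T >= 2)")
    if S.min() < 1 or S.max() > Q:
        raise ValueError(f"symbols must lie in 1..{Q}")
    return S


def estimate_markov(S: np.ndarray, Q: int) -> MarkovModel:
    """Closed-form MLE from a trials x T symbol matrix (symbols 1..Q).

    States with no outgoing transitions receive a uniform transition row;
    states never observed first receive initial probability 0.
    """
    if Q < 2:
        raise ValueError("need Q >= 2 states")
    S = _check_sequences(S, Q)
    S0 = S - 1
    pi = np.bincount(S0[:, 0], minlength=Q).astype(float)
    pi /= pi.sum()
    counts = np.bincount(
        (Q * S0[:, :-1] + S0[:, 1:]).ravel(), minlength=Q * Q
    ).reshape(Q, Q).astype(float)
    out = counts.sum(axis=1)
    Tm = np.where(out[:, None] > 0, counts / np.maximum(out[:, None], 1.0), 1.0 / Q)
    return MarkovModel(pi=pi, Tm=Tm)


def sequence_loglik(S: np.ndarray, model: MarkovModel, floor: float = PROB_FLOOR) -> float:
    """Total log-likelihood of a multi-trial symbol matrix under a chain.

    Zero probabilities are replaced by ``floor`` so the result is finite.
    """
    Q = model.n_states
    S = _check_sequences(S, Q)
    S0 = S - 1
    logpi = np.log(np.maximum(model.pi, floor))
    logT = np.log(np.maximum(model.Tm, floor))
    return float(logpi[S0[:, 0]].sum() + logT[S0[:, :-1], S0[:, 1:]].sum())


def model_distance(
    M1: MarkovModel,
    M2: MarkovModel,
    S1: np.ndarray,
    S2: np.ndarray,
    floor: float = PROB_FLOOR,
) -> float:
    """Symmetrized Rabiner model distance on observed sequences.

    ``D(M1, M2)`` is the per-symbol log-likelihood advantage of ``M1`` over
    ``M2`` on condition 2's sequences; the returned value averages the two
    directions.  It is <= 0 whenever the models are the MLEs of their own
    data, with equality iff the models coincide on the observed transitions.
    """
    if M1.n_states != M2.n_states:
        raise ValueError("models must share the same state count Q")
    S1 = _check_sequences(S1, M1.n_states)
    S2 = _check_sequences(S2, M2.n_states)
    d12 = (sequence_loglik(S2, M1, floor) - sequence_loglik(S2, M2, floor)) / (
        S2.shape[1] * S2.shape[0]
    )
    d21 = (sequence_loglik(S1, M2, floor) - sequence_loglik(S1, M1, floor)) / (
        S1.shape[1] * S1.shape[0]
    )
    return 0.5 * (d12 + d21)


def _mle_distance(S1, S2, Q, floor):
    M1 = estimate_markov(S1, Q)
    M2 = estimate_markov(S2, Q)
    return model_distance(M1, M2, S1, S2, floor)


def permutation_test(
    S1: np.ndarray,
    S2: np.ndarray,
    Q: int,
    n_perm: int = 1000,
    seed=None,
    floor: float = PROB_FLOOR,
) -> tuple[float, np.ndarray, float]:
    """Lower-tail permutation test on the symmetrized model distance.

    Pooled trials are reassigned without replacement to two
    pseudo-conditions of the original sizes; each permutation re-estimates
    both chains and recomputes D_sym.  Returns ``(D_obs, null, p)`` with the
    add-one correction ``p = (1 + #{null <= D_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    S1 = _check_sequences(S1, Q)
    S2 = _check_sequences(S2, Q)
    if S1.shape[0] < 2 or S2.shape[0] < 2:
        raise ValueError("each condition needs at least 2 trials")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d_obs = _mle_distance(S1, S2, Q, floor)
    pooled = np.vstack([S1, S2])
    n1 = S1.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[b] = _mle_distance(pooled[perm[:n1]], pooled[perm[n1:]], Q, floor)
    p = (1.0 + np.sum(null <= d_obs)) / (1.0 + n_perm)
    return d_obs, null, float(p)


def sample_sequences(
    model: MarkovModel, n_trials: int, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample independent symbol sequences (1..Q) from a Markov chain."""
    Q = model.n_states
    S = np.empty((n_trials, T), dtype=int)
    pi_cdf = np.cumsum(model.pi)
    T_cdf = np.cumsum(model.Tm, axis=1)
    u = rng.random((n_trials, T))
    S[:, 0] = np.searchsorted(pi_cdf, u[:, 0])
    for t in range(1, T):
        cdf = T_cdf[S[:, t - 1]]
        S[:, t] = (u[:, t, None] > cdf).sum(axis=1)
    return S + 1


class MarkovChain(BaseEstimator):
    """scikit-learn-style wrapper over the counting MLE.

    Attributes after :meth:`fit`: ``startprob_`` (pi), ``transmat_`` (Tm).
    """

    def __init__(self, n_states: int = 2, floor: float = PROB_FLOOR):
        self.n_states = n_states
        self.floor = floor

    def fit(self, X, y=None):
        model = estimate_markov(np.asarray(X), self.n_states)
        self.startprob_ = model.pi
        self.transmat_ = model.Tm
        return self

    def score(self, X) -> float:
        """Floored total log-likelihood of a symbol matrix."""
        return sequence_loglik(
            np.asarray(X), MarkovModel(self.startprob_, self.transmat_), self.floor
        )

    def model_(self) -> MarkovModel:
        return MarkovModel(self.startprob_, self.transmat_)
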