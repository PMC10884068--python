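"""First-order Markov models: estimation from data and surrogate synthesis.

Markov surrogates are the null model for symbolic-sequence complexity:
a surrogate synthesized from a sequence's empirical transition matrix
preserves the marginal state distribution and all lag-1 structure while
destroying every higher-order dependency.  Metrics that agree between a
sequence and its surrogates are therefore determined by first-order
structure alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqcore import Alphabet, SymbolicSequence

__all__ = ["TransitionModel", "estimate_transition_matrix", "synthesize_surrogate", "shuffle_surrogate"]


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with initial and stationary distributions."""

    P: np.ndarray
    initial: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        A = self.alphabet.size
        if self.P.shape != (A, A):
            raise ValueError(f"transition matrix must be {A}x{A}, got {self.P.shape}")
        if (self.P < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rowsum = self.P.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-12):
            raise ValueError(f"rows must sum to 1; got {rowsum}")
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.initial.shape != (A,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial must be a length-A probability vector")

    def stationary_candidates(self) -> list[np.ndarray]:
        """All unit-eigenvalue left eigenvectors of P normalized to distributions."""
        vals, vecs = np.linalg.eig(self.P.T)
        idx = np.where(np.isclose(vals, 1.0, atol=1e-8))[0]
        candidates = []
        for i in idx:
            v = np.real(vecs[:, i])
            if np.allclose(np.imag(vecs[:, i]), 0, atol=1e-8) and abs(v.sum()) > 1e-12:
                v = v / v.sum()
                if (v >= -1e-10).all():
                    candidates.append(np.clip(v, 0, None) / np.clip(v, 0, None).sum())
        return candidates

    @property
    def stationary(self) -> np.ndarray:
        """The unique stationary distribution; raises for reducible chains."""
        candidates = self.stationary_candidates()
        if not candidates:
            raise ValueError("transition matrix has no stationary distribution")
        if len(candidates) > 1 and not all(
            np.allclose(candidates[0], c, atol=1e-8) for c in candidates[1:]
        ):
            raise ValueError("stationary distribution is not unique (reducible chain)")
        return candidates[0]

    @property
    def A(self) -> int:
        return self.alphabet.size

    @classmethod
    def from_matrix(
        cls, P, initial=None, alphabet: Alphabet | None = None
    ) -> "TransitionModel":
        P = np.asarray(P, dtype=np.float64)
        if alphabet is None:
            alphabet = Alphabet.default(P.shape[0])
        if initial is None:
            initial = np.full(P.shape[0], 1.0 / P.shape[0])
        return cls(P, initial, alphabet)


def estimate_transition_matrix(
    seqs: SymbolicSequence | list[SymbolicSequence],
) -> TransitionModel:
    """Maximum-likelihood transition matrix from one or more sequences.

    P_ij = count(i -> j) / count(i -> any), with transition counts
    pooled across sequences but never bridging sequence boundaries.
    The initial distribution is the pooled empirical symbol frequency.
    States never seen as transition sources get a uniform row (with a
    warning) so that synthesis cannot dead-lock on rare states.
    """
    if isinstance(seqs, SymbolicSequence):
        seqs = [seqs]
    if not seqs:
        raise ValueError("need at least one sequence")
    alphabet = seqs[0].alphabet
    A = alphabet.size
    counts = np.zeros((A, A), dtype=np.int64)
    symbol_counts = np.zeros(A, dtype=np.int64)
    for s in seqs:
        if s.alphabet.size != A:
            raise ValueError("all sequences must share one alphabet size")
        np.add.at(counts, (s.states[:-1], s.states[1:]), 1)
        symbol_counts += np.bincount(s.states, minlength=A)
    row_tot = counts.sum(axis=1)
    P = np.empty((A, A), dtype=np.float64)
    unseen = row_tot == 0
    if unseen.any():
        warnings.warn(
            f"states {np.flatnonzero(unseen).tolist()} never occur as transition "
            "sources; their rows are set to uniform",
            stacklevel=2,
        )
        P[unseen] = 1.0 / A
    P[~unseen] = counts[~unseen] / row_tot[~unseen, None]
    initial = symbol_counts / symbol_counts.sum()
    return TransitionModel(P, initial, alphabet)


@njit(cache=True)
def _synthesize(cum_P, cum_init, n, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(n, dtype=np.int64)
    out[0] = np.searchsorted(cum_init, np.random.random())
    for t in range(1, n):
        out[t] = np.searchsorted(cum_P[out[t - 1]], np.random.random())
    return out


def synthesize_surrogate(
    model: TransitionModel, n: int, seed: int
) -> SymbolicSequence:
    """Synthesize a first-order Markov surrogate of length n.

    X_1 ~ model.initial, X_{t+1} ~ P[X_t, :].  Deterministic given seed.
    """
    if n < 1:
        raise ValueError("surrogate length must be >= 1")
    cum_P = np.cumsum(model.P, axis=1)
    cum_P[:, -1] = 1.0  # guard against round-off at the top end
    cum_init = np.cumsum(model.initial)
    cum_init[-1] = 1.0
    states = _synthesize(cum_P, cum_init, n, seed % (2**31 - 1))
    return SymbolicSequence(
        states, model.alphabet, {"surrogate": "markov1", "seed": seed}
    )


def shuffle_surrogate(
    seq: SymbolicSequence, seed: int
) -> SymbolicSequence:
    """Random permutation of the sequence; preserves only the marginal distribution."""
    rng = np.random.default_rng(seed)
    return SymbolicSequence(
        rng.permutation(seq.states),
        seq.alphabet,
        {**seq.meta, "surrogate": "shuffle", "seed": seed},
    )
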