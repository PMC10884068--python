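"""Block entropies, entropy rate, excess entropy, and partial autoinformation.

For a stationary symbolic process the joint entropy of length-k words
H(X^(k)) grows asymptotically as E + h_X * k: the slope h_X is the
entropy rate (irreducible per-symbol randomness, the Kolmogorov-
complexity facet) and the intercept E is the excess entropy (the mutual
information between the semi-infinite past and future, a statistical-
complexity measure that peaks near phase transitions).  Both are
estimated here by an unweighted least-squares line through the plug-in
block entropies at k = 1..k_max (default 6).

The plug-in (maximum-likelihood) estimator is used deliberately, with
no bias correction: its characteristic from-below convergence of h_X
with sequence length is part of what this package quantifies.  All
entropies are base-2 (bits, bits/sample).

Partial autoinformation (PAI) generalizes partial autocorrelation to
categorical data: pai(k) is the conditional mutual information between
a sample and its lag-k predecessor given the intervening samples.  A
first-order Markov process has pai(k) = 0 for all k >= 2, which makes
the PAI profile a direct test of Markovianity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .markov import TransitionModel
from .seqcore import SymbolicSequence

__all__ = [
    "BlockEntropyProfile",
    "ComplexityEstimate",
    "PAIProfile",
    "block_entropy",
    "block_entropy_profile",
    "entropy_rate_excess",
    "analytic_markov_entropy_rate",
    "pai",
]


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector, 0 log 0 := 0."""
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _word_codes(states: np.ndarray, A: int, k: int) -> np.ndarray:
    """Encode all n-k+1 overlapping length-k windows as base-A integers.

    The first symbol of a window is the most significant digit, so
    ``code // A^(k-1)`` drops to the leading symbol and ``code % A^(k-1)``
    is the word without it.
    """
    n = states.size
    if k > n:
        raise ValueError(f"block length k={k} exceeds sequence length n={n}")
    if A**k > 2**62:
        raise ValueError(f"word space A^k = {A}^{k} overflows the integer encoding")
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * A + states[j : n - k + 1 + j]
    return codes


@dataclass
class BlockEntropyProfile:
    """Plug-in joint entropies H(X^(k)) for k = 1..k_max, in bits."""

    k_values: np.ndarray
    H: np.ndarray
    n_samples: int


@dataclass
class ComplexityEstimate:
    """Entropy rate and excess entropy from the H(k)-vs-k linear fit."""

    h_X: float          # slope, bits/sample
    E: float            # intercept, bits
    fit_residuals: np.ndarray
    k_max: int
    profile: BlockEntropyProfile


@dataclass
class PAIProfile:
    """Partial autoinformation coefficients per lag, in bits."""

    lags: np.ndarray
    pai: np.ndarray


def block_entropy(seq: SymbolicSequence, k: int) -> float:
    """Plug-in Shannon entropy (bits) of the empirical length-k word distribution.

    Words are the n-k+1 overlapping windows of the sequence; counting
    never crosses sequence boundaries.
    """
    if k < 1:
        raise ValueError("block length must be >= 1")
    codes = _word_codes(seq.states, seq.alphabet.size, k)
    return _entropy_bits(np.bincount(codes))


def block_entropy_profile(seq: SymbolicSequence, k_max: int = 6) -> BlockEntropyProfile:
    """H(X^(k)) for k = 1..k_max."""
    ks = np.arange(1, k_max + 1)
    H = np.array([block_entropy(seq, int(k)) for k in ks])
    return BlockEntropyProfile(ks, H, len(seq))


def entropy_rate_excess(seq: SymbolicSequence, k_max: int = 6) -> ComplexityEstimate:
    """Entropy rate h_X and excess entropy E from the block-entropy fit.

    Ordinary least squares through the points (k, H(X^(k))) for
    k = 1..k_max: the slope estimates h_X (bits/sample), the y-axis
    intercept estimates E (bits).

    Warns if the sequence is short relative to the word space A^k_max,
    where the plug-in estimator is biased low.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2 for a two-parameter fit")
    A = seq.alphabet.size
    if len(seq) < A**k_max:
        warnings.warn(
            f"sequence length {len(seq)} < A^k_max = {A**k_max}: "
            "block entropies at large k are undersampled and biased low",
            stacklevel=2,
        )
    prof = block_entropy_profile(seq, k_max)
    fit = scipy.stats.linregress(prof.k_values, prof.H)
    resid = prof.H - (fit.intercept + fit.slope * prof.k_values)
    return ComplexityEstimate(
        h_X=float(fit.slope),
        E=float(fit.intercept),
        fit_residuals=resid,
        k_max=k_max,
        profile=prof,
    )


def analytic_markov_entropy_rate(model: TransitionModel) -> float:
    """Exact entropy rate of a first-order Markov chain, in bits/sample.

    h = -sum_i pi_i sum_j P_ij log2 P_ij with pi the stationary
    distribution (left fixed point of P); 0 log 0 := 0.
    """
    P = model.P
    logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    row_H = -(P * logP).sum(axis=1)
    if np.ptp(row_H) < 1e-12:
        # every state has the same conditional entropy, so the rate does not
        # depend on the stationary weights (covers deterministic chains like
        # the identity, where the stationary distribution is not unique)
        return float(row_H[0])
    return float(model.stationary @ row_H)


def pai(seq: SymbolicSequence, lag_max: int = 5) -> PAIProfile:
    """Partial autoinformation coefficients for lags 0..lag_max.

    pai(0) = H(X_t); pai(1) = I(X_t; X_{t-1}); for k >= 2,
    pai(k) = I(X_t; X_{t-k} | X_{t-k+1}, ..., X_{t-1}).

    Each lag-k coefficient is computed from the single empirical joint
    distribution of (k+1)-words by marginalization, which keeps every
    coefficient non-negative exactly (conditional mutual information of
    a proper joint distribution).
    """
    if lag_max >= len(seq):
        raise ValueError(f"lag_max={lag_max} must be < sequence length {len(seq)}")
    A = seq.alphabet.size
    out = np.empty(lag_max + 1)
    out[0] = block_entropy(seq, 1)
    for k in range(1, lag_max + 1):
        full = np.bincount(_word_codes(seq.states, A, k + 1), minlength=A ** (k + 1))
        # marginals of the (k+1)-word joint: drop first and/or last symbol
        drop_first = full.reshape(A, -1).sum(axis=0)       # (X_{t-k+1..t})
        drop_last = full.reshape(-1, A).sum(axis=1)        # (X_{t-k..t-1})
        middle = drop_first.reshape(-1, A).sum(axis=1)     # (X_{t-k+1..t-1})
        H_mid = _entropy_bits(middle) if k >= 2 else 0.0
        cmi = (
            _entropy_bits(drop_first)
            + _entropy_bits(drop_last)
            - _entropy_bits(full)
            - H_mid
        )
        out[k] = max(cmi, 0.0)  # clip -0.0 from float round-off
    return PAIProfile(np.arange(lag_max + 1), out)
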