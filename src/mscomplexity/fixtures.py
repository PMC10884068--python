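"""Synthetic sequence generator for microstate-like test data.

Every metric in this package can be exercised without any recording:
the generator covers iid noise (known entropy rate log2(A), H = 0.5),
strong-diagonal Markov chains (the dwell-time structure typical of
microstate sequences, whose transition matrices are diagonal-dominant),
deterministic periodic and constant sequences (zero entropy rate /
known PAI saturation), a single-state-flip sequence (the documented
DFA degeneracy), and Potts node time courses (delegated to the
simulator).

All kinds are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import potts
from .markov import TransitionModel, synthesize_surrogate
from .seqcore import Alphabet, SymbolicSequence

__all__ = ["FixtureSpec", "generate", "diagonal_transition_matrix"]

KINDS = (
    "iid-uniform",
    "markov-diagonal",
    "periodic",
    "constant",
    "single-flip",
    "potts-node",
)


def diagonal_transition_matrix(A: int, d: float) -> np.ndarray:
    """P = d * I + (1 - d)/(A - 1) * (ones - I): stay with probability d."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("diagonal weight d must be in [0, 1]")
    off = (1.0 - d) / (A - 1)
    return np.full((A, A), off) + (d - off) * np.eye(A)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic sequence.

    ``params`` per kind: markov-diagonal -> ``d`` (default 0.9, the
    strong diagonal of empirical microstate matrices); periodic ->
    ``period`` (default A); single-flip -> ``flip_at`` (default n//2);
    potts-node -> ``rel_T`` (default 1.0), ``L``, ``warmup``.
    """

    kind: str
    A: int = 4
    n: int = 30_000
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.A < 2 or self.n < 1:
            raise ValueError("need A >= 2 and n >= 1")


def generate(spec: FixtureSpec) -> SymbolicSequence:
    """Generate the sequence a :class:`FixtureSpec` describes."""
    alphabet = Alphabet.default(spec.A)
    rng = np.random.default_rng(spec.seed)
    meta = {"fixture": spec.kind, "seed": spec.seed}

    if spec.kind == "iid-uniform":
        return SymbolicSequence(rng.integers(0, spec.A, spec.n), alphabet, meta)

    if spec.kind == "markov-diagonal":
        d = spec.params.get("d", 0.9)
        model = TransitionModel.from_matrix(
            diagonal_transition_matrix(spec.A, d), alphabet=alphabet
        )
        seq = synthesize_surrogate(model, spec.n, spec.seed)
        return SymbolicSequence(seq.states, alphabet, {**meta, "d": d})

    if spec.kind == "periodic":
        period = spec.params.get("period", spec.A)
        if period > spec.A:
            raise ValueError(f"period {period} needs at least {period} states")
        cycle = np.arange(period, dtype=np.int64)
        reps = -(-spec.n // period)
        return SymbolicSequence(np.tile(cycle, reps)[: spec.n], alphabet, meta)

    if spec.kind == "constant":
        return SymbolicSequence(np.zeros(spec.n, dtype=np.int64), alphabet, meta)

    if spec.kind == "single-flip":
        flip_at = spec.params.get("flip_at", spec.n // 2)
        if not 0 < flip_at < spec.n:
            raise ValueError("flip_at must be strictly inside the sequence")
        states = np.zeros(spec.n, dtype=np.int64)
        states[flip_at:] = 1
        return SymbolicSequence(states, alphabet, {**meta, "flip_at": flip_at})

    # potts-node: one run, one recorded node at the requested temperature
    config = potts.PottsRunConfig(
        L=spec.params.get("L", 25),
        Q=spec.A,
        relative_temperatures=(spec.params.get("rel_T", 1.0),),
        n_iterations=spec.n,
        warmup=spec.params.get("warmup", 2_500),
        n_nodes=1,
        n_runs=1,
        seed=spec.seed,
    )
    seq = potts.simulate(config)[0]
    return SymbolicSequence(seq.states, alphabet, {**meta, **seq.meta})
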