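"""Core data model for symbolic (categorical) time series.

A recording reduced to a label sequence over a small finite alphabet --
an EEG microstate sequence, a Potts-model node time course, a Markov
chain realization -- is represented by :class:`SymbolicSequence`:
integer state codes plus an :class:`Alphabet` mapping codes to display
labels.  All metric modules operate on the integer codes, so a 4-state
microstate sequence (labels A-D) and a Q=4 Potts run share one code
path.

Sequences are read from and written to plain-text files in three
dialects: one label per line, a single comma-separated line, or a
single-column CSV with a header row.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "SymbolicSequence",
    "read_sequence",
    "write_sequence",
    "jump_sequence",
    "apply_partition",
]

_FORMATS = ("lines", "csv", "single-line")


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of display labels mapped to integer codes 0..size-1."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("alphabet needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"alphabet labels not unique: {self.labels}")

    @classmethod
    def default(cls, size: int) -> "Alphabet":
        """Letters A, B, C, ... for up to 26 states, else decimal digits as strings."""
        if size <= 26:
            return cls(tuple(string.ascii_uppercase[:size]))
        return cls(tuple(str(i) for i in range(size)))

    @property
    def size(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> Mapping[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SymbolicSequence:
    """Ordered categorical states with provenance metadata.

    Parameters
    ----------
    states : array-like of int
        State codes, each in ``[0, alphabet.size)``.
    alphabet : Alphabet
        Code-to-label mapping.
    meta : dict
        Free-form provenance (source, seed, temperature, condition ...);
        carried into experiment result tables.
    """

    states: np.ndarray
    alphabet: Alphabet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("states must be a non-empty 1-D array")
        if self.states.min() < 0 or self.states.max() >= self.alphabet.size:
            raise ValueError(
                f"state codes must lie in [0, {self.alphabet.size}); "
                f"found range [{self.states.min()}, {self.states.max()}]"
            )

    def __len__(self) -> int:
        return self.states.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymbolicSequence):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and np.array_equal(self.states, other.states)
        )

    def labels(self) -> list[str]:
        """States rendered as display labels."""
        return [self.alphabet.labels[s] for s in self.states]

    def with_meta(self, **kwargs) -> "SymbolicSequence":
        return SymbolicSequence(self.states, self.alphabet, {**self.meta, **kwargs})

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], alphabet: Alphabet | None = None, meta: dict | None = None
    ) -> "SymbolicSequence":
        labels = list(labels)
        if alphabet is None:
            alphabet = Alphabet(tuple(sorted(set(labels))))
        index = alphabet.index
        try:
            states = [index[lab] for lab in labels]
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in alphabet {alphabet.labels}") from exc
        return cls(np.asarray(states), alphabet, meta or {})


def _tokenize(text: str, fmt: str) -> list[str]:
    if fmt == "lines":
        return [ln.strip() for ln in text.splitlines() if ln.strip()]
    if fmt == "single-line":
        return [tok.strip() for tok in text.replace("\n", "").split(",") if tok.strip()]
    if fmt == "csv":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        return lines[1:]  # drop header
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_sequence(
    path: str | Path,
    format: str = "lines",
    alphabet: Alphabet | None = None,
) -> SymbolicSequence:
    """Read a symbolic sequence from a text file.

    ``alphabet=None`` infers the alphabet as the sorted set of distinct
    tokens; purely numeric tokens are interpreted as integer codes and
    given a default letter alphabet when they fit one.

    Raises
    ------
    ValueError
        If the file is empty or a token is not in the alphabet (the
        error names the offending token and its position).
    """
    path = Path(path)
    tokens = _tokenize(path.read_text(encoding="utf-8"), format)
    if not tokens:
        raise ValueError(f"no sequence tokens found in {path}")
    if alphabet is None and all(tok.lstrip("-").isdigit() for tok in tokens):
        codes = [int(tok) for tok in tokens]
        size = max(codes) + 1
        alphabet = Alphabet(tuple(str(i) for i in range(max(size, 2))))
        tokens = [str(c) for c in codes]
    if alphabet is None:
        alphabet = Alphabet(tuple(sorted(set(tokens))))
    index = alphabet.index
    states = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        if tok not in index:
            raise ValueError(
                f"unknown symbol {tok!r} at token {i + 1} of {path}; "
                f"alphabet is {alphabet.labels}"
            )
        states[i] = index[tok]
    return SymbolicSequence(states, alphabet, {"source": str(path)})


def write_sequence(
    seq: SymbolicSequence, path: str | Path, format: str = "lines"
) -> None:
    """Write a sequence to a text file; inverse of :func:`read_sequence`."""
    path = Path(path)
    labels = seq.labels()
    if format == "lines":
        text = "\n".join(labels) + "\n"
    elif format == "single-line":
        text = ",".join(labels) + "\n"
    elif format == "csv":
        text = "state\n" + "\n".join(labels) + "\n"
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path.write_text(text, encoding="utf-8")


def jump_sequence(seq: SymbolicSequence) -> SymbolicSequence:
    """Collapse consecutive duplicate states (the Markov jump chain).

    ``ACCCAADBBA`` becomes ``ACADBA``: durations are discarded, only
    transitions between distinct states remain.  Idempotent; preserves
    the first state and the relative order of run representatives.
    """
    s = seq.states
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    np.not_equal(s[1:], s[:-1], out=keep[1:])
    return SymbolicSequence(s[keep], seq.alphabet, {**seq.meta, "jump": True})


def apply_partition(
    seq: SymbolicSequence, partition: tuple[Sequence[int], Sequence[int]]
) -> np.ndarray:
    """Embed a categorical sequence as a signed +-1 series.

    ``partition`` is a pair of disjoint state-code subsets covering the
    alphabet exactly; states in the first subset map to +1, the second
    to -1.  This is the random-walk embedding used for DFA.
    """
    plus, minus = (frozenset(partition[0]), frozenset(partition[1]))
    if plus & minus:
        raise ValueError(f"partition subsets overlap: {sorted(plus & minus)}")
    covered = plus | minus
    if covered != set(range(seq.alphabet.size)):
        raise ValueError(
            f"partition {sorted(plus)}|{sorted(minus)} does not cover "
            f"alphabet of size {seq.alphabet.size} exactly"
        )
    signs = np.empty(seq.alphabet.size, dtype=np.int8)
    for a in plus:
        signs[a] = 1
    for a in minus:
        signs[a] = -1
    return signs[seq.states].astype(np.float64)
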