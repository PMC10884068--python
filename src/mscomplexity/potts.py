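"""2D Q-state standard Potts model sampled by Metropolis Monte Carlo.

The standard Potts model places a discrete spin q in {0, ..., Q-1} on
every node of an L x L square lattice.  With ferromagnetic coupling
J = +1 and nearest-neighbour interactions, a site's energy is minus the
number of its four neighbours sharing its state.  A single control
parameter, the temperature T (in units of J), drives the model through
a phase transition at the exactly known critical temperature

    T_c = 1 / ln(1 + sqrt(Q)).

Node time courses sampled across a temperature sweep serve as ground
truth for the complexity metrics: the true dynamical regime (ordered /
critical / disordered) is known by construction, unlike for empirical
microstate sequences.

Conventions (the standard ones for this model): periodic boundary
conditions; one "iteration" is a full sweep of L^2 single-site update
attempts; proposals are uniform over all Q states; the initial grid is
iid uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .seqcore import Alphabet, SymbolicSequence

__all__ = [
    "critical_temperature",
    "LatticeState",
    "PottsRunConfig",
    "site_energy",
    "total_energy",
    "metropolis_iteration",
    "simulate",
    "PAPER_REL_TEMPS",
]

#: The 17-point relative-temperature grid used for the temperature sweep.
PAPER_REL_TEMPS = (
    0.2, 0.4, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2,
    1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0,
)


def critical_temperature(Q: int) -> float:
    """Exact critical temperature of the 2D standard Potts model, 1/ln(1+sqrt(Q))."""
    if Q < 2:
        raise ValueError(f"Potts model needs Q >= 2 states, got {Q}")
    return 1.0 / np.log(1.0 + np.sqrt(Q))


@dataclass
class LatticeState:
    """L x L grid of Potts spins at temperature T."""

    grid: np.ndarray
    T: float
    Q: int

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid, dtype=np.int64)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        if self.grid.shape[0] < 2:
            raise ValueError("lattice size must be >= 2")
        if self.grid.min() < 0 or self.grid.max() >= self.Q:
            raise ValueError(f"grid states must lie in [0, {self.Q})")

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @classmethod
    def random(cls, L: int, Q: int, T: float, rng: np.random.Generator) -> "LatticeState":
        return cls(rng.integers(0, Q, size=(L, L)), T=T, Q=Q)


@dataclass
class PottsRunConfig:
    """Protocol for a temperature-sweep simulation.

    Defaults follow the reference protocol: a 25 x 25 lattice, Q = 4,
    30,000 recorded sweeps after a 2,500-sweep warm-up, 25 randomly
    chosen nodes recorded per run, 50 runs per temperature, over the
    17-point T/T_c grid.
    """

    L: int = 25
    Q: int = 4
    relative_temperatures: tuple[float, ...] = PAPER_REL_TEMPS
    n_iterations: int = 30_000
    warmup: int = 2_500
    n_nodes: int = 25
    n_runs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")
        if not (1 <= self.n_nodes <= self.L**2):
            raise ValueError(f"n_nodes must be in [1, L^2={self.L**2}]")


def site_energy(lattice: LatticeState, k: int, l: int) -> int:
    """Energy of site (k, l): -(number of aligned nearest neighbours), J = +1.

    Periodic boundaries; every site has exactly four neighbours.
    """
    L = lattice.L
    if not (0 <= k < L and 0 <= l < L):
        raise IndexError(f"site ({k}, {l}) outside {L}x{L} lattice")
    g = lattice.grid
    s = g[k, l]
    aligned = (
        int(g[(k - 1) % L, l] == s)
        + int(g[(k + 1) % L, l] == s)
        + int(g[k, (l - 1) % L] == s)
        + int(g[k, (l + 1) % L] == s)
    )
    return -aligned


def total_energy(lattice: LatticeState) -> int:
    """Total lattice Hamiltonian -J * sum over bonds of delta(s_i, s_j).

    Each nearest-neighbour bond is counted once, so the sum of
    :func:`site_energy` over all sites equals twice this value.  The
    critical-temperature formula refers to this Hamiltonian.
    """
    g = lattice.grid
    aligned = (
        (g == np.roll(g, 1, axis=0)).sum() + (g == np.roll(g, 1, axis=1)).sum()
    )
    return -int(aligned)


@njit(cache=True)
def _sweep(grid, Q, T, rand_sites, rand_states, rand_accept):  # pragma: no cover
    """One full sweep: L^2 Metropolis single-site attempts. Returns delta(total E)."""
    L = grid.shape[0]
    dE_total = 0
    for a in range(L * L):
        idx = rand_sites[a]
        k = idx // L
        l = idx % L
        old = grid[k, l]
        new = rand_states[a]
        if new == old:
            continue
        up = grid[(k - 1) % L, l]
        down = grid[(k + 1) % L, l]
        left = grid[k, (l - 1) % L]
        right = grid[k, (l + 1) % L]
        n_old = (up == old) + (down == old) + (left == old) + (right == old)
        n_new = (up == new) + (down == new) + (left == new) + (right == new)
        # Change of the bond-Hamiltonian: only the 4 bonds at (k, l) move.
        dE = -(n_new - n_old)
        if dE <= 0 or rand_accept[a] < np.exp(-dE / T):
            grid[k, l] = new
            dE_total += dE
    return dE_total


@njit(cache=True)
def _run_chain(grid, Q, T, n_sweeps, node_rows, node_cols, seed):  # pragma: no cover
    """Run n_sweeps sweeps, recording the listed nodes once per sweep."""
    np.random.seed(seed)
    L = grid.shape[0]
    n_nodes = node_rows.shape[0]
    out = np.empty((n_sweeps, n_nodes), dtype=np.int64)
    for t in range(n_sweeps):
        rand_sites = np.random.randint(0, L * L, L * L)
        rand_states = np.random.randint(0, Q, L * L)
        rand_accept = np.random.random(L * L)
        _sweep(grid, Q, T, rand_sites, rand_states, rand_accept)
        for j in range(n_nodes):
            out[t, j] = grid[node_rows[j], node_cols[j]]
    return out


def metropolis_iteration(
    lattice: LatticeState, rng: np.random.Generator
) -> LatticeState:
    """Perform one full sweep (L^2 single-site Metropolis attempts) in place.

    Each attempt picks a uniformly random site and proposes a uniformly
    random new state; the move is accepted with probability
    min(1, exp(-dE/T)).  Returns the (mutated) lattice.
    """
    if lattice.T <= 0:
        raise ValueError("Metropolis sampling requires T > 0")
    L = lattice.L
    n = L * L
    _sweep(
        lattice.grid,
        lattice.Q,
        lattice.T,
        rng.integers(0, n, n),
        rng.integers(0, lattice.Q, n),
        rng.random(n),
    )
    return lattice


def simulate(config: PottsRunConfig) -> list[SymbolicSequence]:
    """Run the full temperature-sweep protocol.

    For every temperature and run: draw a random initial grid, discard
    ``warmup`` sweeps, then record ``n_nodes`` randomly chosen lattice
    nodes once per sweep for ``n_iterations`` sweeps.  Node subsets are
    resampled per run.  Deterministic given ``config.seed``.

    Returns one :class:`SymbolicSequence` per (temperature, run, node),
    with ``meta = {"rel_T", "T", "run", "node", "seed"}``.
    """
    Tc = critical_temperature(config.Q)
    alphabet = Alphabet.default(config.Q)
    master = np.random.SeedSequence(config.seed)
    sequences: list[SymbolicSequence] = []
    for rel_T in config.relative_temperatures:
        T = rel_T * Tc
        for run in range(config.n_runs):
            child = master.spawn(1)[0]
            rng = np.random.Generator(np.random.PCG64(child))
            grid = rng.integers(0, config.Q, size=(config.L, config.L))
            nodes = rng.choice(config.L**2, size=config.n_nodes, replace=False)
            node_rows = (nodes // config.L).astype(np.int64)
            node_cols = (nodes % config.L).astype(np.int64)
            chain_seed = int(rng.integers(0, 2**31 - 1))
            total = config.warmup + config.n_iterations
            recorded = _run_chain(
                np.ascontiguousarray(grid, dtype=np.int64),
                config.Q, T, total, node_rows, node_cols, chain_seed,
            )[config.warmup:]
            for j in range(config.n_nodes):
                sequences.append(
                    SymbolicSequence(
                        recorded[:, j],
                        alphabet,
                        {
                            "rel_T": rel_T,
                            "T": T,
                            "run": run,
                            "node": int(nodes[j]),
                            "seed": chain_seed,
                        },
                    )
                )
    return sequences
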