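"""Synchronous Boolean dynamics, attractors and landscape construction.

States are binary vectors over the network's ``n`` nodes; the update is
deterministic and synchronous, so from any initial state the trajectory
eventually enters a cycle (possibly a fixed point).  The set of distinct
cycles — the attractor landscape — is found either exhaustively (all
``2**n`` initial states, small ``n``) or by relaxing a sample of random
initial states (large ``n``), mirroring how such landscapes are surveyed
at the two network sizes studied here (10 and 100 nodes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels
from .network import BooleanNetwork

__all__ = [
    "Attractor",
    "Landscape",
    "UNRESOLVED",
    "step",
    "relax_to_attractor",
    "find_attractors_exhaustive",
    "find_attractors_sampled",
    "canonical_form",
    "successor_table",
    "export_landscape_csv",
]

#: sentinel returned when a trajectory does not close within the step cap
UNRESOLVED = None

#: largest n for which exhaustive state-space enumeration is allowed
EXHAUSTIVE_CAP = 20

#: default step cap for relaxation (transient + period)
DEFAULT_MAX_STEPS = 10_000


def _as_state(net: BooleanNetwork, s: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.ascontiguousarray(s, dtype=np.uint8)
    if arr.shape != (net.n,):
        raise ValueError(f"state must have length {net.n}, got shape {arr.shape}")
    if arr.max(initial=0) > 1:
        raise ValueError("state entries must be 0 or 1")
    return arr


@dataclass(frozen=True)
class Attractor:
    """A cycle of the synchronous dynamics, stored in canonical rotation.

    ``cycle`` is an ``(period, n)`` 0/1 array whose first row is the
    lexicographically smallest state of the cycle, which makes identity
    rotation-invariant: two attractors are the same cycle iff their
    ``cycle`` arrays are equal.
    """

    cycle: np.ndarray

    def __post_init__(self):
        c = np.ascontiguousarray(self.cycle, dtype=np.uint8)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("cycle must be a (period, n) array")
        object.__setattr__(self, "cycle", c)
        c.setflags(write=False)

    @property
    def period(self) -> int:
        return self.cycle.shape[0]

    @property
    def n(self) -> int:
        return self.cycle.shape[1]

    @property
    def key(self) -> bytes:
        """Hashable identity of the canonical cycle."""
        return self.cycle.tobytes()

    @property
    def canonical_id(self) -> str:
        return hashlib.sha1(self.key).hexdigest()[:16]

    def __eq__(self, other):
        if not isinstance(other, Attractor):
            return NotImplemented
        return self.cycle.shape == other.cycle.shape and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __repr__(self):
        return f"Attractor(period={self.period}, n={self.n}, id={self.canonical_id})"


def canonical_form(cycle: np.ndarray | Attractor) -> Attractor:
    """Rotate a cycle so its lexicographically smallest state comes first."""
    arr = cycle.cycle if isinstance(cycle, Attractor) else np.asarray(cycle, dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError("cycle must be a (period, n) array")
    keys = [arr[t].tobytes() for t in range(arr.shape[0])]
    start = min(range(len(keys)), key=keys.__getitem__)
    return Attractor(np.roll(arr, -start, axis=0))


@dataclass
class Landscape:
    """The attractors of a network, plus how they were discovered.

    In ``exhaustive`` mode ``basin_sizes[i]`` counts the initial states
    relaxing into attractor ``i`` (they sum to ``2**n``) and an internal
    state-to-attractor map makes later relaxations a table lookup.  In
    ``sampled`` mode the list covers only what the sampled initial states
    reached, and trajectories that failed to close within the step cap are
    counted in ``unresolved_count`` rather than dropped silently.
    """

    n: int
    attractors: list[Attractor]
    discovery_mode: str  # "exhaustive" | "sampled"
    samples_used: int = 0
    unresolved_count: int = 0
    basin_sizes: np.ndarray | None = None
    _basin_map: np.ndarray | None = field(default=None, repr=False)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a.key: i for i, a in enumerate(self.attractors)}

    def index_of(self, a: Attractor) -> int | None:
        return self._index.get(a.key)

    def add(self, a: Attractor) -> int:
        """Append a new attractor (used when perturbations reach one not yet listed)."""
        if a.key in self._index:
            return self._index[a.key]
        self.attractors.append(a)
        self._index[a.key] = len(self.attractors) - 1
        return len(self.attractors) - 1

    def __len__(self):
        return len(self.attractors)


def step(net: BooleanNetwork, s: Sequence[int] | np.ndarray) -> np.ndarray:
    """One synchronous update: every node reads its inputs' old values."""
    return _kernels.step_array(net.inputs, net.tables, _as_state(net, s))


def relax_to_attractor(
    net: BooleanNetwork,
    s: Sequence[int] | np.ndarray,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor | None:
    """Iterate from ``s`` until the trajectory closes into a cycle.

    Returns the attractor in canonical form, or :data:`UNRESOLVED`
    (``None``) when transient plus period exceed ``max_steps`` — a value,
    not an error, because step-capped surveys record such cases.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    x0 = _as_state(net, s)
    mu, lam, cycle = _kernels.find_cycle(net.inputs, net.tables, x0, max_steps)
    if mu is None:
        return UNRESOLVED
    return canonical_form(cycle)


# ---------------------------------------------------------------------------
# exhaustive enumeration (bit-packed state space)

def _all_states(n: int) -> np.ndarray:
    """(2**n, n) matrix of all states; node 0 is the most significant bit."""
    ints = np.arange(2 ** n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return ((ints[:, None] >> shifts) & 1).astype(np.uint8)

def _pack(states: np.ndarray) -> np.ndarray:
    n = states.shape[-1]
    powers = (1 << np.arange(n - 1, -1, -1)).astype(np.int64)
    return states.astype(np.int64) @ powers


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """Successor of every state, as an array of packed ints (n <= 20)."""
    if net.n > EXHAUSTIVE_CAP:
        raise ValueError(
            f"successor table needs 2**n entries; n={net.n} exceeds the "
            f"cap of {EXHAUSTIVE_CAP} — use sampling instead"
        )
    states = _all_states(net.n)
    return _pack(_kernels.step_many(net.inputs, net.tables, states))


def find_attractors_exhaustive(net: BooleanNetwork) -> Landscape:
    """All attractors and exact basin sizes by scanning every initial state."""
    succ = successor_table(net)
    size = succ.shape[0]
    assign = np.full(size, -1, dtype=np.int64)
    walk_mark = np.full(size, -1, dtype=np.int64)
    attractors: list[Attractor] = []
    cycles_ints: list[np.ndarray] = []

    for s0 in range(size):
        if assign[s0] >= 0:
            continue
        path = []
        s = s0
        while assign[s] < 0 and walk_mark[s] != s0:
            walk_mark[s] = s0
            path.append(s)
            s = int(succ[s])
        if assign[s] >= 0:
            aid = int(assign[s])
        else:
            # new cycle: walk it out from s
            cyc = [s]
            t = int(succ[s])
            while t != s:
                cyc.append(t)
                t = int(succ[t])
            aid = len(attractors)
            cycles_ints.append(np.array(cyc, dtype=np.int64))
            shifts = np.arange(net.n - 1, -1, -1)
            bits = ((np.array(cyc, dtype=np.int64)[:, None] >> shifts) & 1).astype(np.uint8)
            attractors.append(canonical_form(bits))
            assign[np.array(cyc, dtype=np.int64)] = aid
        assign[np.array(path, dtype=np.int64)] = aid

    basins = np.bincount(assign, minlength=len(attractors))
    return Landscape(
        n=net.n,
        attractors=attractors,
        discovery_mode="exhaustive",
        samples_used=size,
        unresolved_count=0,
        basin_sizes=basins,
        _basin_map=assign,
    )


def find_attractors_sampled(
    net: BooleanNetwork,
    n_samples: int = 1000,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
) -> Landscape:
    """Attractors reached from ``n_samples`` uniform random initial states."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    attractors: list[Attractor] = []
    index: dict[bytes, int] = {}
    unresolved = 0
    for _ in range(n_samples):
        x0 = rng.integers(0, 2, size=net.n, dtype=np.uint8)
        a = relax_to_attractor(net, x0, max_steps=max_steps)
        if a is UNRESOLVED:
            unresolved += 1
            continue
        if a.key not in index:
            index[a.key] = len(attractors)
            attractors.append(a)
    return Landscape(
        n=net.n,
        attractors=attractors,
        discovery_mode="sampled",
        samples_used=n_samples,
        unresolved_count=unresolved,
    )


def export_landscape_csv(land: Landscape, path: str | Path) -> None:
    """One row per attractor: id, period, basin size, per-node value sequences."""
    import pandas as pd

    rows = []
    for i, a in enumerate(land.attractors):
        row = {
            "canonical_id": a.canonical_id,
            "period": a.period,
            "basin_size": int(land.basin_sizes[i]) if land.basin_sizes is not None else "",
        }
        for node in range(land.n):
            row[f"node_{node}"] = "|".join(str(v) for v in a.cycle[:, node])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
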