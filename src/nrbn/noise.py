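"""Transient flip noise and the attractor transition graph.

Noise is modeled as transient bit flips applied to states *on* an
attractor: the perturbed state is released and the deterministic dynamics
relaxes back to some attractor (the same one or another).  Flipping every
node in every phase of every attractor yields a complete map of the
jump probabilities — a weighted digraph over attractors encoded as a
left-stochastic matrix ``A`` with ``A[i, j]`` the probability that a flip
applied in attractor ``j`` lands the system in attractor ``i``.

Double flips (two distinct nodes inverted in the same state) probe a
larger noise intensity; their jump probabilities are estimated from
sampled node couples rather than enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .dynamics import (
    DEFAULT_MAX_STEPS,
    UNRESOLVED,
    Landscape,
    relax_to_attractor,
    _pack,
)
from .network import BooleanNetwork

__all__ = [
    "TransitionGraph",
    "flip",
    "build_transition_graph_single",
    "build_transition_graph_double",
    "escape_fraction",
    "export_matrix_csv",
    "export_edge_list_csv",
    "to_graphml",
]

#: how many rounds of newly discovered attractors get columns of their own
DEFAULT_GROWTH_ROUNDS = 3

STOCHASTIC_TOL = 1e-12


@dataclass
class TransitionGraph:
    """Attractor set plus the left-stochastic matrix of flip-induced jumps.

    ``n_initial`` attractors come from the input landscape; columns beyond
    that belong to attractors first reached *by* a perturbation (possible
    only with sampled landscapes).  ``trials[:, j] = (attempted, resolved,
    escaped)`` records how column ``j`` was estimated; probabilities are
    landing counts over resolved trials, so every column sums to one.
    """

    landscape: Landscape
    A: np.ndarray
    flip_arity: int
    n_initial: int
    trials: np.ndarray  # (3, m): attempted, resolved, escaped per column
    unresolved_count: int = 0
    beyond_growth_count: int = 0

    @property
    def n_attractors(self) -> int:
        return self.A.shape[0]

    @property
    def new_attractor_count(self) -> int:
        return self.n_attractors - self.n_initial

    def column_checks(self) -> np.ndarray:
        return np.abs(self.A.sum(axis=0) - 1.0)

    def off_diagonal_mass(self) -> float:
        """Mean over columns of the total escape probability (1 - A_jj)."""
        return float(np.mean(1.0 - np.diag(self.A)))

    def off_diagonal_zero_fraction(self) -> float:
        """Fraction of off-diagonal entries that are exactly zero."""
        m = self.A.shape[0]
        if m < 2:
            return 0.0
        off = ~np.eye(m, dtype=bool)
        return float(np.mean(self.A[off] == 0.0))


def flip(s: Sequence[int] | np.ndarray, nodes: Iterable[int]) -> np.ndarray:
    """Invert one or two bits of a state; an involution on those bits."""
    arr = np.array(s, dtype=np.uint8)
    idx = list(nodes)
    if not 1 <= len(idx) <= 2:
        raise ValueError(f"flip takes 1 or 2 nodes, got {len(idx)}")
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate node id in {idx}")
    for i in idx:
        if not 0 <= i < arr.shape[0]:
            raise ValueError(f"node id {i} out of range for n={arr.shape[0]}")
    arr[idx] ^= 1
    return arr


class _Relaxer:
    """Maps a perturbed state to an attractor index, growing the landscape.

    Uses the exhaustive basin map as a lookup table when the landscape has
    one; otherwise relaxes by stepping.  Landings outside the landscape are
    appended (up to a growth-round budget) so the matrix stays genuinely
    stochastic instead of renormalizing missing mass away.
    """

    def __init__(self, net: BooleanNetwork, land: Landscape, max_steps: int,
                 growth_rounds: int = DEFAULT_GROWTH_ROUNDS):
        self.net = net
        self.land = land
        self.max_steps = max_steps
        self.growth_rounds = growth_rounds
        self.round_of: dict[int, int] = {}
        self.pending: list[int] = []
        self.unresolved = 0
        self.beyond_growth = 0

    def land_index(self, state: np.ndarray, source_round: int) -> int | None:
        if self.land._basin_map is not None:
            return int(self.land._basin_map[int(_pack(state))])
        a = relax_to_attractor(self.net, state, max_steps=self.max_steps)
        if a is UNRESOLVED:
            self.unresolved += 1
            return None
        idx = self.land.index_of(a)
        if idx is not None:
            return idx
        if source_round + 1 > self.growth_rounds:
            self.beyond_growth += 1
            return None
        idx = self.land.add(a)
        self.round_of[idx] = source_round + 1
        self.pending.append(idx)
        return idx


def _assemble(land: Landscape, columns: dict[int, np.ndarray],
              trials: dict[int, tuple[int, int, int]], flip_arity: int,
              n_initial: int, relaxer: _Relaxer) -> TransitionGraph:
    m = len(land)
    A = np.zeros((m, m))
    tri = np.zeros((3, m), dtype=np.int64)
    for j, counts in columns.items():
        attempted, resolved, escaped = trials[j]
        col = np.zeros(m)
        col[: counts.shape[0]] = counts
        if resolved > 0:
            A[:, j] = col / resolved
        else:  # nothing resolved: keep the column stochastic via self-return
            A[j, j] = 1.0
        tri[:, j] = (attempted, resolved, escaped)
    return TransitionGraph(
        landscape=land,
        A=A,
        flip_arity=flip_arity,
        n_initial=n_initial,
        trials=tri,
        unresolved_count=relaxer.unresolved,
        beyond_growth_count=relaxer.beyond_growth,
    )


def build_transition_graph_single(
    net: BooleanNetwork,
    land: Landscape,
    max_steps: int = DEFAULT_MAX_STEPS,
    growth_rounds: int = DEFAULT_GROWTH_ROUNDS,
) -> TransitionGraph:
    """Complete single-flip transition map: every node, every phase.

    For attractor ``j`` with period ``L``, all ``n * L`` flips are applied
    and the landing frequencies become column ``j``.  The construction is
    fully deterministic.  Unresolved relaxations shrink the denominator and
    are reported on the returned graph.
    """
    if len(land) == 0:
        raise ValueError("landscape has no attractors")
    relaxer = _Relaxer(net, land, max_steps, growth_rounds)
    n_initial = len(land)
    columns: dict[int, np.ndarray] = {}
    trials: dict[int, tuple[int, int, int]] = {}

    todo = list(range(n_initial))
    for j in todo:
        relaxer.round_of.setdefault(j, 0)
    while todo:
        j = todo.pop(0)
        src_round = relaxer.round_of.get(j, 0)
        a = land.attractors[j]
        counts = np.zeros(len(land) + 64, dtype=np.int64)
        attempted = resolved = escaped = 0
        for t in range(a.period):
            base = a.cycle[t]
            for node in range(net.n):
                perturbed = base.copy()
                perturbed[node] ^= 1
                attempted += 1
                i = relaxer.land_index(perturbed, src_round)
                if i is None:
                    continue
                if i >= counts.shape[0]:
                    counts = np.concatenate([counts, np.zeros(i + 64, dtype=np.int64)])
                counts[i] += 1
                resolved += 1
                if i != j:
                    escaped += 1
        columns[j] = counts[: len(land)].copy() if counts.shape[0] >= len(land) else counts
        trials[j] = (attempted, resolved, escaped)
        while relaxer.pending:
            todo.append(relaxer.pending.pop())
    return _assemble(land, columns, trials, 1, n_initial, relaxer)


PairRule = int | str | Callable[[int], int]


def _n_pairs(rule: PairRule, period: int) -> int | None:
    """Number of sampled couples for an attractor; None means exhaustive."""
    if rule == "exhaustive":
        return None
    if callable(rule):
        return int(rule(period))
    return int(rule)


def per_period(multiplier: int) -> Callable[[int], int]:
    """Sampling rule scaling the number of couples with the attractor period."""
    return lambda period: multiplier * period


def build_transition_graph_double(
    net: BooleanNetwork,
    land: Landscape,
    pairs_per_attractor: PairRule = 25,
    seed: int = 0,
    max_steps: int = DEFAULT_MAX_STEPS,
    growth_rounds: int = DEFAULT_GROWTH_ROUNDS,
) -> TransitionGraph:
    """Double-flip transition map estimated from sampled node couples.

    Each trial picks a uniform cycle phase and a uniform pair of distinct
    nodes, inverts both bits simultaneously, and relaxes.  The sampling
    rule is an integer (fixed couples per attractor — 25 is the convention
    at 10 nodes), a callable of the period (``per_period(250)`` is the
    convention at 100 nodes), or ``"exhaustive"`` (all pairs, all phases).
    """
    if net.n < 2:
        raise ValueError("double flips need at least 2 nodes")
    if len(land) == 0:
        raise ValueError("landscape has no attractors")
    rng = np.random.default_rng(seed)
    relaxer = _Relaxer(net, land, max_steps, growth_rounds)
    n_initial = len(land)
    columns: dict[int, np.ndarray] = {}
    trials: dict[int, tuple[int, int, int]] = {}

    todo = list(range(n_initial))
    for j in todo:
        relaxer.round_of.setdefault(j, 0)
    while todo:
        j = todo.pop(0)
        src_round = relaxer.round_of.get(j, 0)
        a = land.attractors[j]
        n_trials = _n_pairs(pairs_per_attractor, a.period)
        if n_trials is None:
            plan = [
                (t, x, y)
                for t in range(a.period)
                for x in range(net.n)
                for y in range(x + 1, net.n)
            ]
        else:
            phases = rng.integers(0, a.period, size=n_trials)
            pairs = [_random_pair(rng, net.n) for _ in range(n_trials)]
            plan = [(int(t), x, y) for t, (x, y) in zip(phases, pairs)]
        counts = np.zeros(len(land) + 64, dtype=np.int64)
        attempted = resolved = escaped = 0
        for t, x, y in plan:
            perturbed = a.cycle[t].copy()
            perturbed[x] ^= 1
            perturbed[y] ^= 1
            attempted += 1
            i = relaxer.land_index(perturbed, src_round)
            if i is None:
                continue
            if i >= counts.shape[0]:
                counts = np.concatenate([counts, np.zeros(i + 64, dtype=np.int64)])
            counts[i] += 1
            resolved += 1
            if i != j:
                escaped += 1
        columns[j] = counts[: len(land)].copy() if counts.shape[0] >= len(land) else counts
        trials[j] = (attempted, resolved, escaped)
        while relaxer.pending:
            todo.append(relaxer.pending.pop())
    return _assemble(land, columns, trials, 2, n_initial, relaxer)


def _random_pair(rng: np.random.Generator, n: int) -> tuple[int, int]:
    x = int(rng.integers(n))
    y = int(rng.integers(n - 1))
    if y >= x:
        y += 1
    return x, y


def escape_fraction(g: TransitionGraph, sources: str = "initial") -> float:
    """Percentage of perturbation trials that changed the attractor.

    Trials are pooled (per-trial weighting, not per-attractor averaging)
    over the columns of the input landscape's attractors by default;
    ``sources="all"`` also pools trials spent on attractors first reached
    by a perturbation.
    """
    if sources not in ("initial", "all"):
        raise ValueError("sources must be 'initial' or 'all'")
    upto = g.n_initial if sources == "initial" else g.n_attractors
    resolved = g.trials[1, :upto].sum()
    escaped = g.trials[2, :upto].sum()
    if resolved == 0:
        return 0.0
    return 100.0 * escaped / resolved


# ---------------------------------------------------------------------------
# exports

def export_matrix_csv(g: TransitionGraph, path: str | Path) -> None:
    np.savetxt(path, g.A, delimiter=",")


def export_edge_list_csv(g: TransitionGraph, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"source_id": j, "target_id": i, "probability": g.A[i, j]}
        for j in range(g.n_attractors)
        for i in range(g.n_attractors)
        if g.A[i, j] > 0
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def to_networkx(g: TransitionGraph):
    import networkx as nx

    dg = nx.DiGraph()
    dg.add_nodes_from(range(g.n_attractors))
    for j in range(g.n_attractors):
        for i in range(g.n_attractors):
            if g.A[i, j] > 0:
                dg.add_edge(j, i, weight=float(g.A[i, j]))
    return dg


def to_graphml(g: TransitionGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(g), str(path))


def to_dot(g: TransitionGraph, path: str | Path) -> None:
    lines = ["digraph transitions {"]
    for j in range(g.n_attractors):
        for i in range(g.n_attractors):
            if g.A[i, j] > 0:
                lines.append(f'  {j} -> {i} [label="{g.A[i, j]:.3g}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
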