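"""Threshold ergodic sets: the model's cell types.

Flips are an intense kind of noise, so jumps with very small probability
may be too rare to matter within a cell's lifetime.  Introducing a
threshold ``theta`` and discarding attractor transitions whose probability
does not exceed it breaks the transition graph apart: a *threshold ergodic
set* (TES) is a set of attractors mutually reachable through
above-threshold jumps from which no above-threshold jump escapes.  At
``theta = 0`` a TES is the classical ergodic set; as ``theta`` grows the
sets fragment until every attractor stands alone (a "single-TES",
interpreted as a fully differentiated cell).  Cell differentiation is then
a walk whose accessible region shrinks as noise is reduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .noise import TransitionGraph

__all__ = [
    "TES",
    "TesDecomposition",
    "threshold_edges",
    "compute_tes",
    "tes_ratio_curve",
    "simulate_stochastic_differentiation",
    "export_decomposition_json",
]


@dataclass(frozen=True)
class TES:
    """A terminal set of mutually theta-reachable attractors."""

    attractor_ids: frozenset
    theta: float

    def __post_init__(self):
        if not self.attractor_ids:
            raise ValueError("a TES cannot be empty")

    @property
    def is_single(self) -> bool:
        return len(self.attractor_ids) == 1

    def __contains__(self, i: int) -> bool:
        return i in self.attractor_ids

    def __len__(self):
        return len(self.attractor_ids)


@dataclass
class TesDecomposition:
    """All TESs of a transition graph at one threshold.

    Attractors in no TES are *transient*: the noisy dynamics can still
    escape from them, so they are visited only on the way to absorption.
    ``ratio`` (TES count over attractor count) rises from its value at
    ``theta = 0`` to one as the threshold passes every edge weight.
    """

    theta: float
    tes_list: list[TES]
    transient_attractors: list[int]
    n_attractors: int

    @property
    def ratio(self) -> float:
        return len(self.tes_list) / self.n_attractors

    def tes_of(self, attractor_id: int) -> int | None:
        """Index (into ``tes_list``) of the TES holding an attractor, else None."""
        for k, t in enumerate(self.tes_list):
            if attractor_id in t:
                return k
        return None


def threshold_edges(
    g: TransitionGraph | np.ndarray, theta: float, strict: bool = True
) -> nx.DiGraph:
    """Directed graph of the above-threshold attractor transitions.

    Keeps off-diagonal edges with probability strictly greater than
    ``theta`` (``strict=False`` switches to >=).  Self-returns are never
    edges here: staying put cannot constitute escape or reachability.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    A = g.A if isinstance(g, TransitionGraph) else np.asarray(g)
    m = A.shape[0]
    dg = nx.DiGraph()
    dg.add_nodes_from(range(m))
    keep = (A > theta) if strict else (A >= theta)
    np.fill_diagonal(keep, False)
    for i, j in zip(*np.nonzero(keep)):
        dg.add_edge(int(j), int(i), weight=float(A[i, j]))  # column j -> row i
    return dg


def compute_tes(
    g: TransitionGraph | np.ndarray, theta: float, strict: bool = True
) -> TesDecomposition:
    """Decompose the thresholded graph into TESs and transient attractors.

    A TES is a terminal strongly connected component of the thresholded
    graph: mutually theta-reachable, with no above-threshold edge leaving
    the set.  Singleton components with no outgoing edges qualify as
    single-TESs.
    """
    dg = threshold_edges(g, theta, strict=strict)
    m = dg.number_of_nodes()
    cond = nx.condensation(dg)
    tes_list = []
    transients: list[int] = []
    for comp in nx.topological_sort(cond):
        members = cond.nodes[comp]["members"]
        if cond.out_degree(comp) == 0:
            tes_list.append(TES(attractor_ids=frozenset(members), theta=theta))
        else:
            transients.extend(members)
    tes_list.sort(key=lambda t: min(t.attractor_ids))
    return TesDecomposition(
        theta=theta,
        tes_list=tes_list,
        transient_attractors=sorted(transients),
        n_attractors=m,
    )


def tes_ratio_curve(
    g: TransitionGraph | np.ndarray, strict: bool = True
) -> list[tuple[float, float]]:
    """The step curve of (TES count / attractor count) against theta.

    The decomposition can only change where theta crosses an off-diagonal
    edge weight, so the curve is evaluated at theta = 0 and at every
    distinct weight; it is piecewise constant in between and reaches one
    at the largest off-diagonal weight.
    """
    A = g.A if isinstance(g, TransitionGraph) else np.asarray(g)
    off = A[~np.eye(A.shape[0], dtype=bool)] if A.shape[0] > 1 else np.array([])
    weights = sorted(set(float(w) for w in off if w > 0))
    thetas = [0.0] + [w for w in weights if w > 0]
    return [(t, compute_tes(A, t, strict=strict).ratio) for t in thetas]


def _kernel_at_theta(A: np.ndarray, theta: float, strict: bool = True) -> np.ndarray:
    """Column-stochastic jump kernel at a threshold.

    Sub-threshold off-diagonal mass is folded back into the self-return
    probability: below-threshold flips still happen at the modeled noise
    frequency, they just fail to change the attractor, so each column keeps
    total mass one.
    """
    m = A.shape[0]
    keep = (A > theta) if strict else (A >= theta)
    np.fill_diagonal(keep, True)
    K = np.where(keep, A, 0.0)
    K[np.diag_indices(m)] += 1.0 - K.sum(axis=0)
    return K


def simulate_stochastic_differentiation(
    g: TransitionGraph | np.ndarray,
    start_attractor: int,
    theta_schedule: Sequence[tuple[int, float]],
    seed: int = 0,
    n_steps: int = 100,
    allow_theta_decrease: bool = False,
    strict: bool = True,
) -> list[tuple[int, int, int | None]]:
    """Walk the attractor graph in renormalized time under a noise schedule.

    One step spans the interval between consecutive flips.  The schedule
    lists ``(time, theta)`` change points with non-decreasing thetas —
    differentiation proceeds by noise reduction; pass
    ``allow_theta_decrease=True`` to model induced pluripotency as a noise
    increase.  Returns ``(time, attractor_id, tes_index)`` per step, where
    ``tes_index`` refers to the decomposition at the theta then in force
    (``None`` while in a transient attractor).
    """
    A = g.A if isinstance(g, TransitionGraph) else np.asarray(g)
    m = A.shape[0]
    if not 0 <= start_attractor < m:
        raise ValueError(f"start attractor {start_attractor} out of range")
    sched = sorted(theta_schedule, key=lambda p: p[0])
    if not sched or sched[0][0] != 0:
        sched = [(0, 0.0)] + list(sched)
    thetas = [th for _, th in sched]
    if not allow_theta_decrease and any(b < a for a, b in zip(thetas, thetas[1:])):
        raise ValueError(
            "theta schedule must be non-decreasing (differentiation reduces "
            "noise); pass allow_theta_decrease=True to model induced "
            "pluripotency"
        )
    rng = np.random.default_rng(seed)
    decomps = {th: compute_tes(A, th, strict=strict) for th in set(thetas)}
    kernels = {th: _kernel_at_theta(A, th, strict=strict) for th in set(thetas)}

    cur = start_attractor
    out = []
    k = 0  # index into sched
    for t in range(n_steps):
        while k + 1 < len(sched) and sched[k + 1][0] <= t:
            k += 1
        th = sched[k][1]
        out.append((t, cur, decomps[th].tes_of(cur)))
        cur = int(rng.choice(m, p=kernels[th][:, cur]))
    return out


def export_decomposition_json(dec: TesDecomposition, path: str | Path) -> None:
    doc = {
        "theta": dec.theta,
        "tes": [sorted(t.attractor_ids) for t in dec.tes_list],
        "transients": dec.transient_attractors,
        "ratio": dec.ratio,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def lineage_tree_dot(
    g: TransitionGraph | np.ndarray, thetas: Sequence[float], path: str | Path
) -> None:
    """DOT export of the TES refinement across a theta grid.

    Nodes are TESs at each theta level; an edge links a TES to each TES at
    the next level whose members it contains — the model's differentiation
    lineage diagram.
    """
    levels = [compute_tes(g, th) for th in sorted(thetas)]
    lines = ["digraph lineage {", "  rankdir=TB;"]
    names = {}
    for li, dec in enumerate(levels):
        for ti, t in enumerate(dec.tes_list):
            name = f"L{li}_T{ti}"
            names[(li, ti)] = (name, t)
            label = ",".join(str(i) for i in sorted(t.attractor_ids))
            lines.append(f'  {name} [label="θ={dec.theta:g}: {{{label}}}"];')
    for li in range(len(levels) - 1):
        for ti, t in enumerate(levels[li].tes_list):
            for tj, u in enumerate(levels[li + 1].tes_list):
                if u.attractor_ids <= t.attractor_ids:
                    lines.append(f"  L{li}_T{ti} -> L{li + 1}_T{tj};")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
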