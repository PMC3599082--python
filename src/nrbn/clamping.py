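"""Permanent and semi-permanent node perturbations.

A permanent perturbation (knock-out or over-expression) replaces one
node's Boolean rule with a constant, which genuinely changes the network:
the clamped net has its own attractors, in general different from the
original ones except for the clamped node itself.  This module builds
clamped networks, classifies where a clamped system relaxes relative to
the original landscape, measures the avalanche (how many other genes'
expression patterns change), tests recovery after a semi-permanent
perturbation is released, and detects *switch nodes* — nodes whose
clamping routes every state of a multi-attractor TES to one and the same
target TES, the model's deterministic differentiation signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import (
    DEFAULT_MAX_STEPS,
    EXHAUSTIVE_CAP,
    UNRESOLVED,
    Attractor,
    Landscape,
    find_attractors_exhaustive,
    find_attractors_sampled,
    relax_to_attractor,
    _pack as _pack_state,
)
from .network import BooleanNetwork
from .noise import TransitionGraph, build_transition_graph_single
from .tes import TES, compute_tes, threshold_edges

__all__ = [
    "ClampedNetwork",
    "PerturbationOutcome",
    "SwitchNode",
    "clamp",
    "attractors_equivalent_except",
    "avalanche_size",
    "run_permanent_perturbation",
    "perturbation_survey",
    "find_switch_nodes",
    "switch_nodes_attractor_level",
    "switch_node_scan",
]


@dataclass(frozen=True, eq=False)
class ClampedNetwork(BooleanNetwork):
    """A network with one node's rule replaced by a constant.

    Behaves as a plain :class:`BooleanNetwork` everywhere (same wiring,
    same dynamics API); only the clamped node's truth table differs from
    the base network.
    """

    base: BooleanNetwork | None = None
    clamped_node: int = -1
    clamped_value: int = 0


def clamp(net: BooleanNetwork, node: int, value: int) -> ClampedNetwork:
    """Fix ``node`` permanently to ``value`` (its inputs become irrelevant)."""
    if not 0 <= node < net.n:
        raise ValueError(f"node id {node} out of range for n={net.n}")
    if value not in (0, 1):
        raise ValueError(f"clamped value must be 0 or 1, got {value}")
    tables = net.tables.copy()
    tables[node, :] = value
    base = net.base if isinstance(net, ClampedNetwork) and net.clamped_node == node else net
    return ClampedNetwork(
        n=net.n,
        k_in=net.k_in,
        inputs=net.inputs,
        tables=tables,
        topology=net.topology,
        params=dict(net.params),
        base=base,
        clamped_node=node,
        clamped_value=value,
    )


def attractors_equivalent_except(a: Attractor, b: Attractor, ignore_node: int) -> bool:
    """True if the attractors agree on every node except ``ignore_node``.

    Equivalence requires equal periods and some rotation of ``b`` matching
    ``a`` column-by-column with the ignored node masked out.
    """
    if a.n != b.n:
        raise ValueError("attractors live on networks of different size")
    if a.period != b.period:
        return False
    mask = np.ones(a.n, dtype=bool)
    if 0 <= ignore_node < a.n:
        mask[ignore_node] = False
    am = a.cycle[:, mask]
    bm = b.cycle[:, mask]
    return any(
        np.array_equal(np.roll(bm, -r, axis=0), am) for r in range(b.period)
    )


def avalanche_size(source: Attractor, landing: Attractor, perturbed_node: int) -> int:
    """Number of genes (perturbed one excluded) whose expression changed.

    With equal periods the count is minimized over cyclic alignments.  With
    unequal periods a gene is only unchanged when its pattern is the same
    constant in both attractors; any non-constant pattern at a different
    global period counts as affected.
    """
    mask = np.ones(source.n, dtype=bool)
    if 0 <= perturbed_node < source.n:
        mask[perturbed_node] = False
    am = source.cycle[:, mask]
    bm = landing.cycle[:, mask]
    if source.period == landing.period:
        best = am.shape[1]
        for r in range(landing.period):
            diff = int((np.roll(bm, -r, axis=0) != am).any(axis=0).sum())
            best = min(best, diff)
        return best
    a_const = (am == am[0]).all(axis=0)
    b_const = (bm == bm[0]).all(axis=0)
    unchanged = a_const & b_const & (am[0] == bm[0])
    return int((~unchanged).sum())


@dataclass
class PerturbationOutcome:
    """What one flip-and-hold perturbation did to the system."""

    source_attractor: int
    phase: int
    node: int
    clamped_value: int
    landing: Attractor | None
    classification: str  # equivalent_to_source | equivalent_to_other_original |
    #                      new_attractor | unresolved
    avalanche_size: int | None
    recovery: str = "not_tested"  # recovered_source | other_attractor |
    #                               unresolved | not_tested


def run_permanent_perturbation(
    net: BooleanNetwork,
    land: Landscape,
    attractor: int,
    phase: int,
    node: int,
    test_recovery: bool = True,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> PerturbationOutcome:
    """Flip a node in one attractor phase, hold it there, and classify.

    The node's value in the chosen cycle state is inverted and the node is
    clamped to the inverted value; the clamped system relaxes to one of the
    clamped net's attractors.  That landing is classified against the
    original landscape (equivalence ignores the perturbed node).  For
    landings that are genuinely new, ``test_recovery`` releases the clamp
    (the semi-permanent protocol) and checks whether the original attractor
    is recovered.
    """
    src = land.attractors[attractor]
    if not 0 <= phase < src.period:
        raise ValueError(f"phase {phase} out of range for period {src.period}")
    state = src.cycle[phase].copy()
    value = int(1 - state[node])
    state[node] = value
    cnet = clamp(net, node, value)
    landing = relax_to_attractor(cnet, state, max_steps=max_steps)
    if landing is UNRESOLVED:
        return PerturbationOutcome(attractor, phase, node, value, None, "unresolved", None)

    if attractors_equivalent_except(src, landing, node):
        classification = "equivalent_to_source"
        av = 0
    else:
        av = avalanche_size(src, landing, node)
        classification = "new_attractor"
        for j, other in enumerate(land.attractors):
            if j != attractor and attractors_equivalent_except(other, landing, node):
                classification = "equivalent_to_other_original"
                break

    recovery = "not_tested"
    if test_recovery and classification == "new_attractor":
        back = relax_to_attractor(net, landing.cycle[0], max_steps=max_steps)
        if back is UNRESOLVED:
            recovery = "unresolved"
        elif back == src:
            recovery = "recovered_source"
        else:
            recovery = "other_attractor"
    return PerturbationOutcome(
        attractor, phase, node, value, landing, classification, av, recovery
    )


def perturbation_survey(
    nets: Sequence[BooleanNetwork],
    coverage: float = 1.0,
    landscape_mode: str = "auto",
    n_samples: int = 1000,
    max_steps: int = DEFAULT_MAX_STEPS,
    test_recovery: bool = True,
    seed: int = 0,
):
    """Run flip-and-hold perturbations over an ensemble of networks.

    ``coverage`` is the fraction of (attractor, phase, node) triples
    perturbed per net — 1.0 perturbs them all (the 10-node protocol), 0.2
    samples a fifth of them (the 100-node protocol).  Returns a tidy
    DataFrame with one row per perturbation; aggregate it with
    :func:`survey_panels`.
    """
    import pandas as pd

    if not 0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for net_id, net in enumerate(nets):
        if landscape_mode == "exhaustive" or (
            landscape_mode == "auto" and net.n <= EXHAUSTIVE_CAP
        ):
            land = find_attractors_exhaustive(net)
        else:
            land = find_attractors_sampled(
                net, n_samples=n_samples, max_steps=max_steps,
                seed=int(rng.integers(2 ** 31)),
            )
        triples = [
            (a, t, i)
            for a in range(len(land))
            for t in range(land.attractors[a].period)
            for i in range(net.n)
        ]
        if coverage < 1.0:
            take = max(1, int(round(coverage * len(triples))))
            idx = rng.choice(len(triples), size=take, replace=False)
            triples = [triples[k] for k in idx]
        for a, t, i in triples:
            out = run_permanent_perturbation(
                net, land, a, t, i, test_recovery=test_recovery, max_steps=max_steps
            )
            rows.append(
                {
                    "net_id": net_id,
                    "attractor_id": a,
                    "phase": t,
                    "node": i,
                    "clamped_value": out.clamped_value,
                    "classification": out.classification,
                    "avalanche_size": out.avalanche_size,
                    "recovery": out.recovery,
                }
            )
    return pd.DataFrame(rows)


def survey_panels(df) -> dict:
    """Aggregate a survey into the three outcome panels.

    ``different_attractor``: fraction of resolved perturbations whose
    landing is not equivalent to the source.  ``new_vs_equivalent``: among
    those, the split between genuinely new attractors and attractors
    equivalent to a different original one.  ``recovery``: among new
    attractors tested, the split between recovering the source after
    release and settling elsewhere.
    """
    resolved = df[df.classification != "unresolved"]
    different = resolved[resolved.classification != "equivalent_to_source"]
    new = different[different.classification == "new_attractor"]
    tested = new[new.recovery.isin(["recovered_source", "other_attractor"])]
    return {
        "n_perturbations": int(len(df)),
        "n_unresolved": int((df.classification == "unresolved").sum()),
        "different_attractor": _frac(len(different), len(resolved)),
        "new_among_different": _frac(len(new), len(different)),
        "equivalent_other_among_different": _frac(
            int((different.classification == "equivalent_to_other_original").sum()),
            len(different),
        ),
        "recovered_among_new": _frac(
            int((tested.recovery == "recovered_source").sum()), len(tested)
        ),
        "not_recovered_among_new": _frac(
            int((tested.recovery == "other_attractor").sum()), len(tested)
        ),
    }


def _frac(num: int, den: int) -> float:
    return num / den if den else float("nan")


# ---------------------------------------------------------------------------
# switch nodes (deterministic differentiation)

@dataclass(frozen=True)
class SwitchNode:
    """A (node, value) clamp that routes a whole TES to one target TES."""

    node: int
    value: int
    source_tes: frozenset  # attractor indices in the original landscape
    target_ids: frozenset  # canonical ids of the target TES's attractors
    theta: float


def _clamped_graph(
    net: BooleanNetwork,
    node: int,
    value: int,
    n_samples: int,
    max_steps: int,
    seed: int,
) -> tuple[ClampedNetwork, Landscape, TransitionGraph]:
    cnet = clamp(net, node, value)
    if net.n <= EXHAUSTIVE_CAP:
        cland = find_attractors_exhaustive(cnet)
    else:
        cland = find_attractors_sampled(
            cnet, n_samples=n_samples, max_steps=max_steps, seed=seed
        )
    cgraph = build_transition_graph_single(cnet, cland, max_steps=max_steps)
    return cnet, cland, cgraph


def _reachable_tes(
    cgraph: TransitionGraph, theta: float, strict: bool
) -> tuple[list[TES], dict[int, frozenset]]:
    """Per attractor of the clamped graph: which TESs it can evolve into."""
    import networkx as nx

    dec = compute_tes(cgraph, theta, strict=strict)
    dg = threshold_edges(cgraph, theta, strict=strict)
    tes_index: dict[int, int] = {}
    for k, t in enumerate(dec.tes_list):
        for a in t.attractor_ids:
            tes_index[a] = k
    reach: dict[int, frozenset] = {}
    for a in dg.nodes:
        down = nx.descendants(dg, a) | {a}
        reach[a] = frozenset(tes_index[b] for b in down if b in tes_index)
    return dec.tes_list, reach


def _qualifying_pairs(
    net: BooleanNetwork,
    land: Landscape,
    sources: Sequence[TES],
    theta: float,
    strict: bool,
    n_samples: int,
    max_steps: int,
    seed: int,
    cache: dict | None,
) -> list[SwitchNode]:
    """(node, value) clamps routing every state of a source TES to one TES.

    For each candidate clamp, the node is set to the clamp value in every
    phase of every attractor of the source TES, the clamped system
    relaxes, and the landing is assigned within the clamped net's own
    transition graph at ``theta``.  The pair qualifies only if every start
    can evolve into exactly one TES of the clamped graph and it is the
    same TES for all starts.
    """
    out: list[SwitchNode] = []
    for node in range(net.n):
        for value in (0, 1):
            key = (node, value)
            if cache is not None and key in cache:
                cnet, cland, cgraph = cache[key]
            else:
                cnet, cland, cgraph = _clamped_graph(
                    net, node, value, n_samples, max_steps, seed
                )
                if cache is not None:
                    cache[key] = (cnet, cland, cgraph)
            tes_list, reach = _reachable_tes(cgraph, theta, strict)
            for src in sources:
                targets: set[frozenset] = set()
                ok = True
                for a in src.attractor_ids:
                    attr = land.attractors[a]
                    for t in range(attr.period):
                        state = attr.cycle[t].copy()
                        state[node] = value
                        if cland._basin_map is not None:
                            idx = int(cland._basin_map[int(_pack_state(state))])
                        else:
                            landing = relax_to_attractor(cnet, state, max_steps=max_steps)
                            idx = None if landing is UNRESOLVED else cland.index_of(landing)
                        if idx is None:
                            ok = False
                            break
                        r = reach[idx]
                        if len(r) != 1:
                            ok = False
                            break
                        targets.add(r)
                        if len(targets) > 1:
                            ok = False
                            break
                    if not ok:
                        break
                if ok and len(targets) == 1:
                    tk = next(iter(next(iter(targets))))
                    tes = tes_list[tk]
                    out.append(
                        SwitchNode(
                            node=node,
                            value=value,
                            source_tes=frozenset(src.attractor_ids),
                            target_ids=frozenset(
                                cland.attractors[i].canonical_id
                                for i in tes.attractor_ids
                            ),
                            theta=theta,
                        )
                    )
    return out


def find_switch_nodes(
    net: BooleanNetwork,
    g: TransitionGraph,
    theta: float,
    strict: bool = True,
    n_samples: int = 1000,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
    _cache: dict | None = None,
) -> list[SwitchNode]:
    """All (node, value) clamps that deterministically route a TES.

    Sources are the multi-attractor TESs of ``g`` at ``theta``; landings
    are assigned within the clamped net's own transition graph at the same
    threshold.  An empty list is a perfectly normal result: only a
    minority of nets possess switch nodes.
    """
    dec = compute_tes(g, theta, strict=strict)
    sources = [t for t in dec.tes_list if not t.is_single]
    if not sources:
        return []
    return _qualifying_pairs(
        net, g.landscape, sources, theta, strict, n_samples, max_steps, seed, _cache
    )


def switch_nodes_attractor_level(
    net: BooleanNetwork,
    g: TransitionGraph,
    theta: float = 0.0,
    strict: bool = True,
    n_samples: int = 1000,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
) -> list[SwitchNode]:
    """Switch nodes under the strict attractor-level criterion.

    A clamp qualifies when every phase of every attractor of a
    multi-attractor TES at ``theta`` relaxes to one and the same attractor
    of the clamped net — the operational form of deterministic
    differentiation: whatever the cell's state within the multipotent TES,
    the perturbation always drives it down the same pathway to the same
    final expression pattern.  This is stricter than TES-level routing
    (:func:`find_switch_nodes`): only a minority of nets possess such
    nodes.
    """
    land = g.landscape
    dec = compute_tes(g, theta, strict=strict)
    sources = [t for t in dec.tes_list if not t.is_single]
    out: list[SwitchNode] = []
    for node in range(net.n):
        for value in (0, 1):
            cnet = clamp(net, node, value)
            if net.n <= EXHAUSTIVE_CAP:
                cland = find_attractors_exhaustive(cnet)
            else:
                cland = find_attractors_sampled(
                    cnet, n_samples=n_samples, max_steps=max_steps, seed=seed
                )
            for src in sources:
                landings: set[int] = set()
                ok = True
                for a in src.attractor_ids:
                    attr = land.attractors[a]
                    for t in range(attr.period):
                        state = attr.cycle[t].copy()
                        state[node] = value
                        if cland._basin_map is not None:
                            idx = int(cland._basin_map[int(_pack_state(state))])
                        else:
                            landing = relax_to_attractor(cnet, state, max_steps=max_steps)
                            idx = None if landing is UNRESOLVED else cland.index_of(landing)
                        if idx is None:
                            ok = False
                            break
                        landings.add(idx)
                        if len(landings) > 1:
                            ok = False
                            break
                    if not ok:
                        break
                if ok and len(landings) == 1:
                    out.append(
                        SwitchNode(
                            node=node,
                            value=value,
                            source_tes=frozenset(src.attractor_ids),
                            target_ids=frozenset(
                                {cland.attractors[next(iter(landings))].canonical_id}
                            ),
                            theta=theta,
                        )
                    )
    return out


def switch_node_scan(
    net: BooleanNetwork,
    g: TransitionGraph,
    level: str = "attractor",
    strict: bool = True,
    n_samples: int = 1000,
    max_steps: int = DEFAULT_MAX_STEPS,
    seed: int = 0,
) -> list[SwitchNode]:
    """Does this net possess switch nodes?  Scan and return them all.

    ``level="attractor"`` (default) applies the strict criterion — one
    common landing attractor for every state of a multi-attractor TES at
    zero threshold (:func:`switch_nodes_attractor_level`).
    ``level="tes"`` applies the TES-routing criterion at every threshold
    on the graph's edge-weight grid that still has a multi-attractor TES,
    reusing the threshold-independent clamped transition graphs across the
    grid.
    """
    A = g.A
    m = A.shape[0]
    if m < 2:
        return []
    if level == "attractor":
        return switch_nodes_attractor_level(
            net, g, 0.0, strict=strict, n_samples=n_samples,
            max_steps=max_steps, seed=seed,
        )
    if level != "tes":
        raise ValueError("level must be 'attractor' or 'tes'")
    off = A[~np.eye(m, dtype=bool)]
    grid = [0.0] + sorted(set(float(w) for w in off if w > 0))
    cache: dict = {}
    found: list[SwitchNode] = []
    for theta in grid:
        if theta >= 1.0:
            continue
        dec = compute_tes(g, theta, strict=strict)
        if all(t.is_single for t in dec.tes_list):
            continue
        found.extend(
            find_switch_nodes(
                net, g, theta, strict=strict, n_samples=n_samples,
                max_steps=max_steps, seed=seed, _cache=cache,
            )
        )
    return found
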