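# nrbn — noisy random Boolean networks and cell differentiation

`nrbn` implements a dynamical model of cell differentiation built on noisy
random Boolean networks (NRBNs).  A random Boolean network — `N` binary
genes, fixed in-degree `k_in`, random truth tables with bias `p`, synchronous
updates — settles into attractors: the stable gene-activation patterns of
one genome.  Transient single-bit flips (noise) kick the system between
attractors; recording where every flip lands gives a left-stochastic
**attractor transition matrix** `A`, with `A[i,j]` the probability that a
flip in attractor `j` lands the system in attractor `i`.

Discarding jumps with probability ≤ θ and taking terminal strongly
connected components yields the **threshold ergodic sets** (TES_θ): sets of
attractors that entrap the noisy dynamics.  The model's central reading is
TES = cell type.  At θ = 0 (high noise) one large ergodic set is the
totipotent state; as noise falls (θ rises) the set fragments — stochastic
differentiation — until every attractor is a single-TES, a fully
differentiated type.  Within a TES the occupation probabilities evolve by
the master equation `P_{k+1} = A P_k` toward a unique stationary `π = Aπ`
whenever all self-returns are positive.  Permanently clamping a gene to 0
or 1 changes the network itself: it models knock-out/over-expression,
yields avalanches of changed gene patterns, and exposes **switch genes**
whose clamping routes a whole multipotent TES to a single fate
(deterministic differentiation).

The package covers: network generation (critical Erdős–Rényi and
scale-free out-degree with `P(0) = p₀`, `P(k) ∝ k^{−γ}`), exhaustive and
sampled attractor landscapes, single/double-flip transition graphs, TES
decomposition and differentiation walks, Markov/spectral analysis,
clamping surveys, and seeded ensemble experiments.  See
[docs/methods.md](docs/methods.md) for the numerical conventions.

## A worked example

```python
from nrbn import (generate_er_network, find_attractors_exhaustive,
                  build_transition_graph_single, compute_tes)

net = generate_er_network(n=10, k_in=2, bias=0.5, seed=42)
land = find_attractors_exhaustive(net)
g = build_transition_graph_single(net, land)
for theta in (0.0, 0.02, 0.1):
    dec = compute_tes(g, theta)
    print(theta, [sorted(t.attractor_ids) for t in dec.tes_list],
          "transients:", dec.transient_attractors)
```

prints

```
0.0 [[0, 1, 2]] transients: []
0.02 [[0, 1, 2]] transients: []
0.1 [[0, 1]] transients: [2]
```

At high noise (θ ≤ 0.02) the three attractors form one ergodic set — one
multipotent cell type.  At θ = 0.1 the rare jumps are pruned: attractors 0
and 1 still trap the dynamics together (a smaller, more differentiated
TES), while attractor 2 has become transient — a cell found there is
eventually captured by the {0, 1} type, a differentiation event.

The `examples/` scripts walk one capability each (landscapes, TESs,
occupation dynamics, differentiation walks, clamping/switch genes, the
escape table); each prints a couple of annotated numbers and runs in
seconds.  The `nrbn` command exposes the same pipeline from the shell:
`nrbn generate` → `nrbn attractors` → `nrbn transitions` → `nrbn tes`,
passing files between stages.

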