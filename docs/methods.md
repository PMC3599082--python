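# Methods

## The model

A random Boolean network (RBN) is a directed graph of `N` binary genes.
Each node `i` has exactly `k_in` inputs drawn without replacement from the
other `N − 1` nodes (no self-inputs, no duplicated sources) and an explicit
truth table over the `2**k_in` input configurations, each output bit set to
1 with probability `p` at generation time.  Topology and rules are
*quenched* — fixed for the network's lifetime.  Updating is synchronous and
deterministic, so every trajectory ends in a cycle (an attractor, possibly
a fixed point).  All work here uses the critical regime `k_in = 2`,
`p = 1/2`.

Noise enters as *transient flips*: a randomly chosen bit of a state lying
on an attractor is inverted and the deterministic dynamics then relaxes.
The model assumes flips are rare enough that relaxation always completes
between them.  Recording, for every attractor `j`, where each flip lands
yields the left-stochastic attractor transition matrix `A` (`A[i, j]` =
probability that a flip in `j` lands in `i`; columns sum to one).

A *threshold ergodic set* (TES) at threshold `θ` is a set of attractors
mutually reachable through jumps with probability strictly greater than
`θ`, from which no such jump escapes — computed as the terminal strongly
connected components of the thresholded graph, self-loops excluded.  At
`θ = 0` this is the classical ergodic set; raising `θ` (i.e., lowering the
cell's noise) fragments it until every attractor is a single-TES.  The
biological reading: TES = cell type, multi-attractor TES = multipotent,
single-TES = fully differentiated, and differentiation = entrapment in a
smaller TES as noise falls.

Within a TES the renormalized-time jump process (one step per flip) is an
irreducible finite Markov chain `P_{k+1} = A P_k`; if additionally every
self-return probability is positive the chain is aperiodic and the
occupation vector converges to the unique stationary `π = Aπ` from any
initial condition, geometrically at rate `|λ₂|/|λ₁|` (the decaying
convention; the convergence-step estimator also reports the empirical
iteration count, and the two are cross-checked in the tests).

Permanent perturbations (*clamping*) replace one node's rule with a
constant — a different network with its own attractors.  The flip-and-hold
protocol inverts a node's bit in one attractor phase and clamps it there;
the landing is classified against the original landscape, where two
attractors are *equivalent* when they agree, up to cyclic alignment, on
every node except the clamped one.  The *avalanche* is the number of other
genes whose expression pattern changed.

## Scale-free variant

Out-degrees follow a truncated power law with an explicit zero-degree
mass: `P(0) = p₀`, `P(k) ∝ k^−γ` for `1 ≤ k ≤ k_max = N − 1`, with
`p₀ = 0.13` (the Poisson zero-out-degree mass of the matched
Erdős–Rényi ensemble) and `γ` keyed to size (2.24 at N=100, 2.29 at
N=200, 2.34 at N=1000 — values that make the mean out-degree equal
`k_in`, so ER and SF nets carry identical link totals).  The wiring is a
configuration model: degree sequences are rejection-sampled until they
sum to exactly `N·k_in` (the spec of a realizable sequence), stubs are
shuffled and dealt `k_in` per node, and local swap repairs remove
self-loops and duplicate inputs.  In-degree stays exactly `k_in`; only
the out-degree is scale-free.  How the source publications wired their
scale-free nets is not stated; the configuration model is the simplest
scheme preserving both constraints and is flagged as a modeling choice.

## Numerical choices

- **States** are bit vectors externally and bit-packed internally; node 0
  is the most significant bit, so lexicographic order on states equals
  integer order.  Attractor identity is the canonical rotation starting
  at the lexicographically smallest state.
- **Cycle detection** uses Brent's algorithm (numba-compiled when
  available, with an exact pure-Python fallback); for `N ≤ 20` the full
  successor table over `2^N` states is built instead, giving exact basins
  and O(1) relaxation lookups.
- **Step caps**: relaxation defaults to 10 000 steps; the ensemble
  experiment protocol at `N = 100` uses a 1000-step cap with 1000 sampled
  initial conditions per net (the sample count of the source protocol is
  unstated; 1000 gives stable attractor counts at desk scale).
  Trajectories that fail to close are counted as *unresolved* — a value,
  never an exception — and excluded from transition-probability
  denominators with the count reported.
- **Threshold comparison is strict** (`> θ`); a flag flips the
  convention.  Self-loops never contribute to reachability or escape.
- **Sub-threshold mass** in the differentiation walk is folded into the
  self-return probability (sub-threshold flips still occur, they just
  fail to change the attractor), keeping each column stochastic.
- **Landscape growth**: with sampled landscapes a flip can land on an
  attractor not yet listed; it is appended and given its own column, up
  to three growth rounds, after which such landings join the unresolved
  count.  Escape percentages pool trials per net over the *initial*
  landscape's attractors (per-trial weighting), and ensembles average
  net-level percentages; bootstrap CIs (1000 resamples of nets) quantify
  spread, since the source reports no ensemble sizes or error bars.
- **Convergence**: power iteration stops when successive occupation
  vectors differ by `< tol` (max-norm, default 1e-10); the eigen route
  normalizes the unit eigenvector to sum one and clips components above
  −1e-12.  Reducible matrices raise and direct the caller to a TES
  restriction; `stationary_per_tes` automates that.
- **Avalanches** with equal periods minimize the changed-gene count over
  cyclic alignments; with unequal periods a gene counts as unchanged only
  when constant and equal in both attractors (a non-constant pattern at a
  different global period cannot match).

## Switch-node criteria

Deterministic differentiation needs *switch genes* whose clamping always
routes a multipotent TES down one pathway.  The sources state the idea
twice, at two strengths, and give no ensemble protocol, so both are
implemented:

- `find_switch_nodes(net, g, θ)` — TES-level: every phase of every
  attractor of a multi-attractor TES at `θ` must, after clamping, be able
  to evolve into exactly one TES of the clamped net's own transition
  graph at the same `θ`, the same TES for all starts.
- `switch_nodes_attractor_level(net, g, θ=0)` — attractor-level (the
  operational wording: same landing attractor whatever the phase and
  whatever the attractor): every start must relax to one common attractor
  of the clamped net.  This is the default for `switch_node_scan` and for
  the prevalence statistic, because it is the strictest stated form and
  needs no invented threshold schedule.

Whether the target assignment should use the original or the clamped
net's graph is likewise unstated; the clamped graph is used (the clamp is
permanent, so the system lives in the clamped net's landscape), and the
choice is configurable in the code.

## What the generator emulates, and what it does not

Synthetic ensembles reproduce the *statistical* conditions of the study —
sizes 10 and 100, critical wiring, unbiased rules, matched ER/SF link
totals — not any particular biological network.  Passing tests therefore
say the algorithms are correct and the ensemble statistics are stable
under these conditions; they say nothing about real gene networks, whose
in-degrees vary, whose rules are biased toward canalizing functions, and
whose noise is not i.i.d. single-bit flipping.  Sampled landscapes at
N=100 see only attractors whose basins are large enough to be hit by 1000
random starts, exactly as in the source protocol; rare attractors are
under-represented and escape percentages inherit that bias.

## Known limitations

- Measured double-flip escape runs ~1.6–1.9× the single-flip rate, as
  near-independent perturbation propagation predicts (`1−(1−p)² ≈ 2p`);
  the published comparison table instead reports the two rates as nearly
  equal.  No protocol variant consistent with simultaneous two-node flips
  reproduces that equality (sequential and value-constrained couple
  variants were measured too); the discrepancy is reported, not tuned
  away.
- Switch-node prevalence depends on an unstated protocol; under every
  reading implemented here it is bounded below by the probability that a
  net has a multi-attractor ergodic set (~0.5 at N=10), above the
  published "about 1/3".  The attractor-level default lands near the top
  of that band and the statistic is seed-sensitive at 60-net ensembles.
- The "new attractor" fraction of the clamping survey is resolution
  bound: with 1000 sampled initial states a 100-node net's landscape
  omits small-basin attractors, so landings equivalent to an unseen
  original are classified new.  At this resolution the fraction *rises*
  from 10 to 100 nodes rather than falling as the source reports; deeper
  sampling shifts it downward, but the source's sampling depth is
  unstated.
- Wandering simulations treat a threshold change as happening between
  flips; whether it should coincide with a flip event is unspecified and
  the difference is one step.
- Multi-node simultaneous clamping (induced pluripotency with several
  genes) is out of scope.
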