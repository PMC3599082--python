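"""Permanent perturbations: knock-outs, avalanches and switch genes.

Clamping a node to a constant changes the network itself; the system then
relaxes to an attractor of the clamped net.  The landing may be the old
attractor in disguise, a different old attractor, or something genuinely
new — and releasing the clamp does not always restore the original
pattern.  Switch genes route every state of a multipotent TES to one and
the same fate: deterministic differentiation.
"""

from nrbn import (
    build_transition_graph_single,
    find_attractors_exhaustive,
    generate_er_network,
    run_permanent_perturbation,
    switch_node_scan,
)

net = generate_er_network(n=10, k_in=2, bias=0.5, seed=3)
land = find_attractors_exhaustive(net)
g = build_transition_graph_single(net, land)
print(f"net has {len(land)} attractors")

out = run_permanent_perturbation(net, land, attractor=0, phase=0, node=3)
print(f"clamp node 3 in attractor 0: landing is {out.classification}, "
      f"avalanche touches {out.avalanche_size} other genes, "
      f"recovery after release: {out.recovery}")

switches = switch_node_scan(net, g)
if switches:
    sw = switches[0]
    print(f"switch gene found: clamping node {sw.node} to {sw.value} drives "
          f"every state of TES {sorted(sw.source_tes)} to one attractor")
else:
    print("no switch gene in this net (true of most nets)")
# The avalanche is the knock-out footprint: how many genes' expression
# patterns changed as a consequence of permanently silencing one.
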