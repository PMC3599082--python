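"""Generate a critical random Boolean network and map its attractors.

A 10-node net with fixed in-degree 2 and unbiased random rules sits at
the critical boundary between ordered and chaotic dynamics.  Every one of
the 1024 states relaxes into some attractor; the basin sizes say how much
of state space each stable expression pattern drains.
"""

from nrbn import find_attractors_exhaustive, generate_er_network

net = generate_er_network(n=10, k_in=2, bias=0.5, seed=7)
land = find_attractors_exhaustive(net)

print(f"{len(land)} attractors found over {2 ** net.n} states")
for i, a in enumerate(land.attractors):
    print(
        f"  attractor {i}: period {a.period}, basin {int(land.basin_sizes[i])} states, "
        f"first state {''.join(map(str, a.cycle[0]))}"
    )
# Each line is one stable gene-activation pattern: the period is the cycle
# length (1 = steady expression), and the basin counts the initial
# conditions that end up there.
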