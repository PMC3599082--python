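"""Stochastic differentiation as a random walk under falling noise.

One renormalized time step spans the interval between flips.  Raising the
threshold mid-run models a drop in cellular noise: the walk, previously
free to wander the whole ergodic set, becomes trapped in whichever
sub-TES it occupied when the noise fell — that is stochastic
differentiation, and the trapped set is the new, more specialized type.
"""

from collections import Counter

from nrbn import simulate_stochastic_differentiation
from nrbn.fixtures import figure1_like_matrix
from nrbn.tes import tes_ratio_curve

A = figure1_like_matrix()
print("ratio curve:", [(round(t, 3), round(r, 2)) for t, r in tes_ratio_curve(A)])

theta_high = 0.04
for run_seed in range(3):
    traj = simulate_stochastic_differentiation(
        A, start_attractor=0,
        theta_schedule=[(0, 0.0), (200, theta_high)],
        seed=run_seed, n_steps=400,
    )
    before = Counter(a for t, a, _ in traj if t < 200)
    after = Counter(a for t, a, _ in traj if t >= 200)
    final_tes = traj[-1][2]
    print(f"seed {run_seed}: visited {sorted(before)} while noisy; after the "
          f"noise drop passed through {sorted(after)} and settled in "
          f"TES {final_tes} (attractor {traj[-1][1]})")
# Different runs settle in different sub-TESs: identical cells, different
# fates, decided by where the flip noise happened to leave them.
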