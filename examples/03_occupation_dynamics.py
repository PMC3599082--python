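"""Occupation-number dynamics on an attractor transition matrix.

Within a TES the jump process is an irreducible Markov chain; when every
attractor has a positive self-return probability the occupation vector
converges to a unique stationary distribution, regardless of where the
cell starts.  The spectral gap |lambda_2| sets how many flips that takes.
"""

import numpy as np

from nrbn.fixtures import figure1_like_matrix
from nrbn.markov import check_conditions, convergence_steps, restrict, stationary_power
from nrbn.tes import compute_tes

A = figure1_like_matrix()
dec = compute_tes(A, 0.0)
members = sorted(dec.tes_list[0].attractor_ids)
B = restrict(A, members)

print("TES members:", members, "irreducible/aperiodic:", check_conditions(B))
pi, iters = stationary_power(B)
print("stationary occupation:", np.round(pi, 4), f"({iters} iterations)")

rep = convergence_steps(B, tol=1e-8)
print(f"convergence steps: empirical {rep.k_star_empirical}, "
      f"spectral estimate {rep.k_star_spectral}, "
      f"decay ratio |l2|/|l1| = {rep.spectral_gap_ratio:.3f}")
# The stationary vector is the fraction of (renormalized) time a noisy
# cell spends in each attractor of its TES.
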