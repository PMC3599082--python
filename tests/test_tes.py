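import numpy as np
import pytest

from conftest import random_column_stochastic
from nrbn.fixtures import figure1_like_matrix
from nrbn.markov import restrict, stationary_power
from nrbn.tes import (
    compute_tes,
    simulate_stochastic_differentiation,
    tes_ratio_curve,
    threshold_edges,
)


def brute_force_tes(A, theta):
    """Independent oracle: boolean transitive closure, then terminal check."""
    m = A.shape[0]
    E = A > theta
    np.fill_diagonal(E, False)
    # reachability via repeated squaring of the adjacency (row j -> col i)
    R = E.T.astype(int)
    for _ in range(m):
        R = ((R + R @ R) > 0).astype(int)
    R = R.astype(bool)
    mutual = R & R.T
    tes, transients = [], []
    assigned = set()
    for j in range(m):
        if j in assigned:
            continue
        comp = {j} | {i for i in range(m) if mutual[j, i]}
        assigned |= comp
        # escape: any member reaching a non-member
        escapes = any(R[a, b] for a in comp for b in range(m) if b not in comp)
        if not escapes:
            tes.append(frozenset(comp))
        else:
            transients.extend(comp)
    return set(tes), sorted(transients)


@pytest.mark.parametrize("seed", range(30))
def test_compute_tes_matches_reachability_oracle(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 9))
    A = random_column_stochastic(rng, m)
    for theta in [0.0, 0.02, float(rng.uniform(0, 0.3))]:
        dec = compute_tes(A, theta)
        tes_set = {t.attractor_ids for t in dec.tes_list}
        oracle_tes, oracle_trans = brute_force_tes(A, theta)
        assert tes_set == oracle_tes
        assert dec.transient_attractors == oracle_trans


def test_threshold_edges_extremes():
    A = figure1_like_matrix()
    assert threshold_edges(A, 1.0).number_of_edges() == 0
    g0 = threshold_edges(A, 0.0)
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    assert g0.number_of_edges() == int((off > 0).sum())


def test_threshold_strictness_toggles_single_edge():
    A = figure1_like_matrix()
    w = 0.05  # an existing edge weight
    n_above = threshold_edges(A, w).number_of_edges()
    n_at = threshold_edges(A, w, strict=False).number_of_edges()
    eps_below = threshold_edges(A, w - 1e-9).number_of_edges()
    assert n_at == eps_below  # >= at w keeps the weight-w edge
    assert n_above == n_at - 1  # strict > drops exactly it


def test_figure1_like_threshold_prunes_weak_edges():
    A = figure1_like_matrix()
    g = threshold_edges(A, 0.02)
    kept = {(j, i) for j, i in g.edges}
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    expect = {(j, i) for i, j in zip(*np.nonzero(off > 0.02))}
    assert kept == expect


def test_identity_matrix_all_single_tes():
    dec = compute_tes(np.eye(4), 0.0)
    assert len(dec.tes_list) == 4
    assert all(t.is_single for t in dec.tes_list)
    assert dec.ratio == 1.0
    assert tes_ratio_curve(np.eye(4)) == [(0.0, 1.0)]


def test_theta_above_max_weight_gives_all_singles():
    rng = np.random.default_rng(5)
    A = random_column_stochastic(rng, 6)
    off = A[~np.eye(6, dtype=bool)]
    dec = compute_tes(A, float(off.max()))
    assert len(dec.tes_list) == 6 and dec.ratio == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_ratio_curve_monotone_and_piecewise_constant(seed):
    rng = np.random.default_rng(seed + 50)
    A = random_column_stochastic(rng, int(rng.integers(3, 8)))
    curve = tes_ratio_curve(A)
    ratios = [r for _, r in curve]
    assert ratios == sorted(ratios)
    assert curve[-1][1] == 1.0
    # dense-grid oracle: between grid points the decomposition is constant
    thetas = [t for t, _ in curve]
    for (t0, r0), t1 in zip(curve, thetas[1:] + [1.0]):
        for frac in (0.25, 0.75):
            mid = t0 + (t1 - t0) * frac
            assert compute_tes(A, mid).ratio == pytest.approx(r0)


def test_tes_membership_monotone_refinement():
    """A TES at a higher threshold is contained in the TES at a lower one."""
    rng = np.random.default_rng(77)
    A = random_column_stochastic(rng, 7)
    grid = [t for t, _ in tes_ratio_curve(A)]
    for lo, hi in zip(grid, grid[1:]):
        dlo, dhi = compute_tes(A, lo), compute_tes(A, hi)
        for t in dhi.tes_list:
            member = next(iter(t.attractor_ids))
            klo = dlo.tes_of(member)
            if klo is not None:
                assert t.attractor_ids <= dlo.tes_list[klo].attractor_ids


def test_simulation_constant_above_all_weights():
    A = figure1_like_matrix()
    off = A[~np.eye(A.shape[0], dtype=bool)]
    theta = float(off.max())
    traj = simulate_stochastic_differentiation(A, 2, [(0, theta)], seed=0, n_steps=50)
    assert all(a == 2 for _, a, _ in traj)


def test_simulation_entrapment_within_tes():
    """While theta is constant the walk never leaves its current TES."""
    A = figure1_like_matrix()
    for theta in [0.0, 0.02, 0.07]:
        dec = compute_tes(A, theta)
        traj = simulate_stochastic_differentiation(A, 0, [(0, theta)], seed=3, n_steps=300)
        tes_seen = [k for _, _, k in traj if k is not None]
        if tes_seen:
            # once absorbed, the TES index never changes
            first = tes_seen[0]
            assert all(k == first for k in tes_seen)


def test_simulation_longrun_matches_stationary():
    """At theta=0 on an irreducible aperiodic graph, visit frequencies
    approach the stationary distribution of the kernel."""
    rng = np.random.default_rng(1)
    A = random_column_stochastic(rng, 4, zero_frac=0.0, diag_boost=2.0)
    traj = simulate_stochastic_differentiation(A, 0, [(0, 0.0)], seed=2, n_steps=40_000)
    visits = np.bincount([a for _, a, _ in traj], minlength=4) / len(traj)
    pi, _ = stationary_power(A)
    assert np.abs(visits - pi).max() < 0.02


def test_simulation_split_confines_to_sub_tes():
    A = figure1_like_matrix()
    curve = tes_ratio_curve(A)
    theta_hi = curve[-1][0]  # all singles here
    traj = simulate_stochastic_differentiation(
        A, 0, [(0, 0.0), (100, theta_hi)], seed=4, n_steps=200
    )
    # after the switch the walk is frozen in whatever attractor it occupied
    after = [a for t, a, _ in traj if t >= 100]
    assert len(set(after)) == 1


def test_schedule_must_not_decrease_without_flag():
    A = figure1_like_matrix()
    with pytest.raises(ValueError, match="non-decreasing"):
        simulate_stochastic_differentiation(A, 0, [(0, 0.1), (10, 0.0)], seed=0)
    # induced pluripotency: allowed when explicitly requested
    simulate_stochastic_differentiation(
        A, 0, [(0, 0.1), (10, 0.0)], seed=0, n_steps=20, allow_theta_decrease=True
    )


def test_lineage_tree_dot_export(tmp_path):
    """The lineage DOT nests each higher-theta TES under its parent."""
    from nrbn.tes import lineage_tree_dot

    A = figure1_like_matrix()
    p = tmp_path / "lineage.dot"
    lineage_tree_dot(A, [0.0, 0.04, 0.2], p)
    text = p.read_text()
    assert text.startswith("digraph")
    # one node per TES per level
    for li, theta in enumerate([0.0, 0.04, 0.2]):
        n_tes = len(compute_tes(A, theta).tes_list)
        assert sum(f"L{li}_T{k} [" in text for k in range(n_tes)) == n_tes
    # containment edges exist from the root ergodic set to the next level
    assert "L0_T0 -> L1_T0;" in text
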