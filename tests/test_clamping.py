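import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrbn.clamping import (
    attractors_equivalent_except,
    avalanche_size,
    clamp,
    find_switch_nodes,
    perturbation_survey,
    run_permanent_perturbation,
    survey_panels,
    switch_node_scan,
)
from nrbn.dynamics import (
    Attractor,
    canonical_form,
    find_attractors_exhaustive,
    relax_to_attractor,
    step,
)
from nrbn.network import BooleanNetwork, generate_er_network
from nrbn.noise import build_transition_graph_single
from nrbn.tes import compute_tes, threshold_edges


def test_clamp_fixes_bit_and_preserves_rest():
    net = generate_er_network(10, 2, 0.5, seed=0)
    c = clamp(net, 3, 1)
    assert (c.tables[3] == 1).all()
    mask = np.ones(10, dtype=bool)
    mask[3] = False
    assert np.array_equal(c.tables[mask], net.tables[mask])
    assert np.array_equal(c.inputs, net.inputs)
    # after one step the clamped bit holds its value forever
    s = np.zeros(10, dtype=np.uint8)
    for _ in range(5):
        s = step(c, s)
        assert s[3] == 1


def test_clamp_idempotent_and_validated():
    net = generate_er_network(8, 2, 0.5, seed=1)
    once = clamp(net, 2, 0)
    twice = clamp(once, 2, 0)
    assert once == twice
    assert twice.base == net
    with pytest.raises(ValueError):
        clamp(net, 99, 0)
    with pytest.raises(ValueError):
        clamp(net, 0, 2)


def test_clamped_attractors_match_exhaustive_oracle():
    """The clamped net's landscape is just the landscape of its tables."""
    net = generate_er_network(8, 2, 0.5, seed=5)
    c = clamp(net, 0, 1)
    land = find_attractors_exhaustive(c)
    # every attractor holds the clamped value everywhere
    for a in land.attractors:
        assert (a.cycle[:, 0] == 1).all()
    assert land.basin_sizes.sum() == 256


def _attr(rows):
    return canonical_form(np.array(rows, dtype=np.uint8))


def test_equivalence_examples():
    a = _attr([[0, 1, 1]])
    b = _attr([[0, 1, 0]])  # differs only at node 2
    assert attractors_equivalent_except(a, a, 0)
    assert attractors_equivalent_except(a, b, 2)
    assert not attractors_equivalent_except(a, b, 1)
    # different periods are never equivalent
    c = _attr([[0, 1, 1], [1, 1, 1]])
    assert not attractors_equivalent_except(a, c, 0)


def brute_rotation_equivalent(a, b, ignore):
    if a.period != b.period:
        return False
    cols = [i for i in range(a.n) if i != ignore]
    for r in range(b.period):
        rolled = np.roll(b.cycle, -r, axis=0)
        if all(np.array_equal(rolled[:, i], a.cycle[:, i]) for i in cols):
            return True
    return False


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), ignore=st.integers(0, 4))
def test_equivalence_matches_rotation_oracle(seed, ignore):
    rng = np.random.default_rng(seed)
    period = int(rng.integers(1, 5))
    a = _attr(rng.integers(0, 2, size=(period, 5)))
    # b: maybe a rotated/masked copy, maybe fresh noise
    if rng.random() < 0.5:
        rows = np.roll(a.cycle.copy(), int(rng.integers(period)), axis=0)
        if rng.random() < 0.5:
            rows = rows.copy()
            rows[:, ignore] = rng.integers(0, 2, size=period)
    else:
        rows = rng.integers(0, 2, size=(period, 5))
    try:
        b = _attr(rows)
    except ValueError:
        return  # duplicate states: not a valid cycle
    assert attractors_equivalent_except(a, b, ignore) == brute_rotation_equivalent(a, b, ignore)


def test_equivalence_is_equivalence_relation():
    rng = np.random.default_rng(8)
    attrs = [_attr(rng.integers(0, 2, size=(1, 4))) for _ in range(6)]
    for x in attrs:
        assert attractors_equivalent_except(x, x, 0)  # reflexive
        for y in attrs:
            assert attractors_equivalent_except(x, y, 0) == attractors_equivalent_except(y, x, 0)
            for z in attrs:
                if attractors_equivalent_except(x, y, 0) and attractors_equivalent_except(y, z, 0):
                    assert attractors_equivalent_except(x, z, 0)


def test_avalanche_zero_iff_equivalent():
    a = _attr([[0, 1, 1, 0]])
    b = _attr([[1, 1, 1, 0]])
    assert avalanche_size(a, b, 0) == 0
    c = _attr([[1, 0, 0, 1]])
    assert avalanche_size(a, c, 0) == 3  # all but the ignored node changed


def test_perturbation_on_constant_net_is_equivalent_to_source(constant_net):
    land = find_attractors_exhaustive(constant_net)
    out = run_permanent_perturbation(constant_net, land, 0, 0, 2)
    assert out.classification == "equivalent_to_source"
    assert out.avalanche_size == 0
    assert out.recovery == "not_tested"


@pytest.mark.parametrize("seed", range(4))
def test_perturbation_classification_against_exhaustive_oracle(seed):
    """Re-derive the landing and its class by hand for every case of one net."""
    net = generate_er_network(8, 2, 0.5, seed=seed)
    land = find_attractors_exhaustive(net)
    for a_idx, a in enumerate(land.attractors):
        for phase in range(a.period):
            for node in range(8):
                out = run_permanent_perturbation(net, land, a_idx, phase, node)
                state = a.cycle[phase].copy()
                state[node] ^= 1
                cnet = clamp(net, node, int(state[node]))
                landing = relax_to_attractor(cnet, state)
                assert out.landing == landing
                assert 0 <= out.avalanche_size <= 7
                if out.classification == "equivalent_to_source":
                    assert attractors_equivalent_except(a, landing, node)
                    assert out.avalanche_size == 0
                elif out.classification == "equivalent_to_other_original":
                    assert any(
                        attractors_equivalent_except(o, landing, node)
                        for k, o in enumerate(land.attractors)
                        if k != a_idx
                    )
                else:
                    assert not any(
                        attractors_equivalent_except(o, landing, node)
                        for o in land.attractors
                    )


def test_survey_constant_ensemble_all_equivalent(constant_net):
    df = perturbation_survey([constant_net])
    assert (df.classification == "equivalent_to_source").all()
    panels = survey_panels(df)
    assert panels["different_attractor"] == 0.0


def test_survey_composition_and_split_sums(critical_nets10):
    nets = critical_nets10[:3]
    df = perturbation_survey(nets, seed=0)
    panels = survey_panels(df)
    assert 0.0 <= panels["different_attractor"] <= 1.0
    if not np.isnan(panels["new_among_different"]):
        assert panels["new_among_different"] + panels["equivalent_other_among_different"] == pytest.approx(1.0)
    if not np.isnan(panels["recovered_among_new"]):
        assert panels["recovered_among_new"] + panels["not_recovered_among_new"] == pytest.approx(1.0)
    # composition: the survey rows equal direct calls
    land0 = find_attractors_exhaustive(nets[0])
    row = df[(df.net_id == 0)].iloc[0]
    direct = run_permanent_perturbation(
        nets[0], land0, int(row.attractor_id), int(row.phase), int(row.node)
    )
    assert direct.classification == row.classification
    assert direct.avalanche_size == row.avalanche_size


def test_survey_coverage_fraction(critical_nets10):
    net = critical_nets10[0]
    land = find_attractors_exhaustive(net)
    total = sum(a.period for a in land.attractors) * net.n
    df = perturbation_survey([net], coverage=0.5, seed=1)
    assert len(df) == max(1, round(0.5 * total))


def test_find_switch_nodes_empty_without_multi_tes(constant_net):
    land = find_attractors_exhaustive(constant_net)
    g = build_transition_graph_single(constant_net, land)
    assert find_switch_nodes(constant_net, g, 0.0) == []


def _replay_switch_pair(net, g, sw):
    """Independent replay: every start must reach the recorded target TES."""
    land = g.landscape
    cnet = clamp(net, sw.node, sw.value)
    cland = find_attractors_exhaustive(cnet)
    cgraph = build_transition_graph_single(cnet, cland)
    dec = compute_tes(cgraph, sw.theta)
    dg = threshold_edges(cgraph, sw.theta)
    import networkx as nx

    for a in sw.source_tes:
        attr = land.attractors[a]
        for t in range(attr.period):
            s = attr.cycle[t].copy()
            s[sw.node] = sw.value
            landing = relax_to_attractor(cnet, s)
            idx = cland.index_of(landing)
            down = nx.descendants(dg, idx) | {idx}
            reach = {
                k
                for k, tes in enumerate(dec.tes_list)
                for b in down
                if b in tes.attractor_ids
            }
            assert len(reach) == 1
            target = dec.tes_list[next(iter(reach))]
            ids = {cland.attractors[i].canonical_id for i in target.attractor_ids}
            assert ids == set(sw.target_ids)


def test_switch_nodes_verified_by_replay(critical_nets10):
    found_any = False
    for net in critical_nets10:
        land = find_attractors_exhaustive(net)
        g = build_transition_graph_single(net, land)
        for sw in find_switch_nodes(net, g, 0.0)[:3]:
            _replay_switch_pair(net, g, sw)
            found_any = True
        if found_any:
            break
    assert found_any, "seeded ensemble should contain at least one switch pair"


def test_switch_scan_attractor_level_is_subset_of_landings(critical_nets10):
    """Attractor-level switch pairs send every source state to one basin."""
    for net in critical_nets10[:6]:
        land = find_attractors_exhaustive(net)
        g = build_transition_graph_single(net, land)
        for sw in switch_node_scan(net, g)[:2]:
            cnet = clamp(net, sw.node, sw.value)
            cland = find_attractors_exhaustive(cnet)
            landings = set()
            for a in sw.source_tes:
                attr = land.attractors[a]
                for t in range(attr.period):
                    s = attr.cycle[t].copy()
                    s[sw.node] = sw.value
                    landings.add(cland.index_of(relax_to_attractor(cnet, s)))
            assert len(landings) == 1
            assert {cland.attractors[next(iter(landings))].canonical_id} == set(sw.target_ids)
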