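import json

import numpy as np
import pytest
from scipy import stats

from nrbn.network import (
    BooleanNetwork,
    DegreeLaw,
    NetworkFormatError,
    default_gamma,
    generate_er_network,
    generate_sf_network,
    read_network,
    sample_out_degrees,
    to_graphml,
    write_network,
)


@pytest.mark.parametrize("seed", [0, 1, 7])
@pytest.mark.parametrize("n,k_in", [(10, 2), (20, 3), (5, 1)])
def test_er_wiring_invariants(n, k_in, seed):
    net = generate_er_network(n, k_in, 0.5, seed)
    assert net.inputs.shape == (n, k_in)
    for i in range(n):
        row = net.inputs[i].tolist()
        assert len(set(row)) == k_in, "duplicate input source"
        assert i not in row, "self-input"
    assert net.tables.shape == (n, 2 ** k_in)
    assert net.out_degrees().sum() == n * k_in


def test_er_seed_determinism(tmp_path):
    a = generate_er_network(10, 2, 0.5, seed=42)
    b = generate_er_network(10, 2, 0.5, seed=42)
    assert a == b
    write_network(a, tmp_path / "a.json")
    write_network(b, tmp_path / "b.json")
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
    assert a != generate_er_network(10, 2, 0.5, seed=43)


@pytest.mark.parametrize("bias,value", [(1.0, 1), (0.0, 0)])
def test_er_degenerate_bias(bias, value):
    net = generate_er_network(10, 2, bias, seed=0)
    assert (net.tables == value).all()


def test_er_bias_pooled_fraction():
    # binomial counting oracle: 300 nets x 10 nodes x 4 rows, p = 0.5
    total = ones = 0
    for s in range(300):
        t = generate_er_network(10, 2, 0.5, seed=s).tables
        ones += int(t.sum())
        total += t.size
    p_hat = ones / total
    sigma = np.sqrt(0.25 / total)
    assert abs(p_hat - 0.5) < 3 * sigma


def test_er_invalid_parameters():
    with pytest.raises(ValueError):
        generate_er_network(5, 5, 0.5, seed=0)  # k_in >= n
    with pytest.raises(ValueError):
        generate_er_network(5, 2, 1.5, seed=0)


def test_degree_law_normalization():
    for gamma, p0 in [(2.24, 0.13), (2.34, 0.13), (3.0, 0.0), (1.5, 0.4)]:
        law = DegreeLaw(gamma=gamma, p0=p0)
        pmf = law.pmf(100)
        assert abs(pmf.sum() - 1.0) < 1e-12
        assert pmf[0] == pytest.approx(p0)
        # z' definition: p(k) = k^-gamma / z' for k >= 1
        ks = np.arange(1, 100)
        assert np.allclose(pmf[1:], ks ** -gamma / law.z_prime(100))


def test_out_degree_zero_frequency():
    law = DegreeLaw(gamma=2.24, p0=0.13)
    draws = sample_out_degrees(law, 100_000, seed=5)
    f0 = np.mean(draws == 0)
    sigma = np.sqrt(0.13 * 0.87 / 100_000)
    assert abs(f0 - 0.13) < 3 * sigma


def test_out_degree_distribution_gof():
    """Sampled out-degrees match the truncated power law (chi-square)."""
    law = DegreeLaw(gamma=2.34, p0=0.13, k_max=99)
    draws = sample_out_degrees(law, 50_000, seed=11)
    pmf = law.pmf(100)
    # pool the sparse tail so expected counts stay above 5
    edges = [0, 1, 2, 3, 4, 5, 7, 10, 100]
    obs = np.histogram(draws, bins=edges)[0]
    exp = np.array([pmf[lo:hi].sum() for lo, hi in zip(edges[:-1], edges[1:])]) * len(draws)
    chi2 = stats.chisquare(obs, exp)
    assert chi2.pvalue > 0.01


def test_out_degree_large_gamma_limit():
    law = DegreeLaw(gamma=50.0, p0=0.0)
    draws = sample_out_degrees(law, 10_000, seed=2)
    assert (draws == 1).all()


@pytest.mark.parametrize("seed", range(5))
def test_sf_network_invariants(seed):
    net = generate_sf_network(100, 2, 0.5, seed=seed)
    # stub conservation: fixed in-degree, scale-free out-degree
    assert (np.ones(100) * 2 == [len(set(r)) for r in net.inputs.tolist()]).all()
    assert net.out_degrees().sum() == 200
    for i in range(100):
        assert i not in net.inputs[i]
    # matched link totals with the ER ensemble
    er = generate_er_network(100, 2, 0.5, seed=seed)
    assert er.n_links() == net.n_links() == 200


def test_sf_out_degree_ensemble_gof():
    """Pooled out-degrees over an SF ensemble follow the degree law."""
    law = DegreeLaw(gamma=2.24, p0=0.13)
    degs = np.concatenate(
        [generate_sf_network(100, 2, 0.5, law, seed=s).out_degrees() for s in range(40)]
    )
    pmf = law.pmf(100)
    edges = [0, 1, 2, 3, 4, 5, 7, 10, 100]
    obs = np.histogram(degs, bins=edges)[0]
    exp = np.array([pmf[lo:hi].sum() for lo, hi in zip(edges[:-1], edges[1:])]) * len(degs)
    # conditioning on the exact stub total slightly distorts the tail; test
    # at the same significance as the unconditioned sampler
    chi2 = stats.chisquare(obs, exp)
    assert chi2.pvalue > 0.01


def test_sf_default_gamma_by_size():
    assert default_gamma(100) == 2.24
    assert default_gamma(200) == 2.29
    assert default_gamma(1000) == 2.34
    with pytest.raises(ValueError):
        default_gamma(37)


def test_network_roundtrip(tmp_path):
    for net in [
        generate_er_network(10, 2, 0.5, seed=1),
        generate_sf_network(100, 2, 0.5, seed=1),
    ]:
        p = tmp_path / "net.json"
        write_network(net, p)
        back = read_network(p)
        assert back == net
        assert back.params == net.params


def test_read_network_invariant_violations(tmp_path):
    net = generate_er_network(6, 2, 0.5, seed=0)
    p = tmp_path / "net.json"
    write_network(net, p)
    doc = json.loads(p.read_text())

    bad = json.loads(json.dumps(doc))
    bad["nodes"][0]["inputs"] = [1, 2, 3]  # three inputs with k_in = 2
    q = tmp_path / "bad1.json"
    q.write_text(json.dumps(bad))
    with pytest.raises(NetworkFormatError, match="inputs"):
        read_network(q)

    bad = json.loads(json.dumps(doc))
    bad["nodes"][2]["table"] = bad["nodes"][2]["table"][:-1]  # missing a row
    q = tmp_path / "bad2.json"
    q.write_text(json.dumps(bad))
    with pytest.raises(NetworkFormatError, match="table"):
        read_network(q)

    bad = json.loads(json.dumps(doc))
    bad["nodes"][3]["inputs"][0] = 3  # self-input
    q = tmp_path / "bad3.json"
    q.write_text(json.dumps(bad))
    with pytest.raises(NetworkFormatError, match="self-input"):
        read_network(q)


def test_graphml_export(tmp_path):
    import networkx as nx

    net = generate_er_network(8, 2, 0.5, seed=0)
    p = tmp_path / "net.graphml"
    to_graphml(net, p)
    g = nx.read_graphml(p)
    assert g.number_of_edges() == 16
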