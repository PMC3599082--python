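"""Generation and serialization of quenched random Boolean networks.

A network is a directed graph of ``n`` binary genes.  Every node receives
exactly ``k_in`` inputs and carries an explicit truth table mapping each of
the ``2**k_in`` input configurations to an output bit.  Two wiring schemes
are supported:

* ``erdos_renyi`` — inputs drawn uniformly without replacement from the
  other ``n - 1`` nodes, so the *out*-degree distribution is approximately
  Poisson with mean ``k_in``;
* ``scale_free`` — the out-degree of each node is drawn from a truncated
  power law with an explicit probability of zero out-degree, and the wiring
  is realized with a configuration-model scheme that keeps the in-degree
  fixed at ``k_in``.

Networks are *quenched*: topology and rules never change after generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "BooleanNetwork",
    "DegreeLaw",
    "GenerationError",
    "NetworkFormatError",
    "default_gamma",
    "generate_er_network",
    "generate_sf_network",
    "sample_out_degrees",
    "read_network",
    "write_network",
    "to_graphml",
]

#: scale-free exponents keyed to network size
_GAMMA_BY_SIZE = {100: 2.24, 200: 2.29, 1000: 2.34}


class GenerationError(RuntimeError):
    """Raised when a random construction cannot be realized."""

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


class NetworkFormatError(ValueError):
    """Raised when a serialized network violates the format or an invariant."""


def default_gamma(n: int) -> float:
    """Scale-free exponent used for the standard network sizes.

    The exponents are calibrated so that the mean out-degree equals the
    fixed in-degree (2), keeping the total link count of a scale-free net
    equal to that of the matched Erdős–Rényi net.
    """
    try:
        return _GAMMA_BY_SIZE[n]
    except KeyError:
        raise ValueError(
            f"no default scale-free exponent for n={n}; "
            f"known sizes: {sorted(_GAMMA_BY_SIZE)} — pass gamma explicitly"
        ) from None


@dataclass(frozen=True)
class DegreeLaw:
    """Truncated power-law out-degree distribution with a point mass at zero.

    ``P(k) = p0`` for ``k = 0`` and ``P(k) = k**-gamma / z_prime`` for
    ``k in 1..k_max``, where ``z_prime = sum(k**-gamma) / (1 - p0)`` so the
    probabilities sum to one.
    """

    gamma: float
    p0: float = 0.0
    k_max: int = 0  # 0 means "set from n at sampling time" (n - 1)

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not 0.0 <= self.p0 < 1.0:
            raise ValueError(f"p0 must be in [0, 1), got {self.p0}")

    def resolve_k_max(self, n: int) -> int:
        return self.k_max if self.k_max > 0 else n - 1

    def z_prime(self, n: int) -> float:
        k_max = self.resolve_k_max(n)
        k = np.arange(1, k_max + 1, dtype=float)
        return float(np.sum(k ** -self.gamma) / (1.0 - self.p0))

    def pmf(self, n: int) -> np.ndarray:
        """Probabilities over k = 0 .. k_max (sums to 1)."""
        k_max = self.resolve_k_max(n)
        k = np.arange(1, k_max + 1, dtype=float)
        body = k ** -self.gamma
        p = np.empty(k_max + 1)
        p[0] = self.p0
        p[1:] = (1.0 - self.p0) * body / body.sum()
        return p


@dataclass(frozen=True)
class BooleanNetwork:
    """A quenched Boolean network: fixed wiring plus per-node truth tables.

    ``inputs[i]`` lists the ``k_in`` distinct source nodes feeding node
    ``i``; ``tables[i]`` has ``2**k_in`` output bits, indexed so that the
    value of ``inputs[i][0]`` is the most significant bit of the row index.
    """

    n: int
    k_in: int
    inputs: np.ndarray  # (n, k_in) int32
    tables: np.ndarray  # (n, 2**k_in) uint8
    topology: str = "erdos_renyi"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        inputs = np.ascontiguousarray(self.inputs, dtype=np.int32)
        tables = np.ascontiguousarray(self.tables, dtype=np.uint8)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "tables", tables)
        self._validate()
        inputs.setflags(write=False)
        tables.setflags(write=False)

    def _validate(self):
        n, k = self.n, self.k_in
        if self.inputs.shape != (n, k):
            raise NetworkFormatError(
                f"inputs must have shape {(n, k)}, got {self.inputs.shape}"
            )
        if self.tables.shape != (n, 2 ** k):
            raise NetworkFormatError(
                f"truth tables must have shape {(n, 2 ** k)}, "
                f"got {self.tables.shape}"
            )
        if self.inputs.min(initial=0) < 0 or self.inputs.max(initial=0) >= n:
            raise NetworkFormatError("input ids out of range")
        for i in range(n):
            row = self.inputs[i]
            if len(set(row.tolist())) != k:
                raise NetworkFormatError(f"node {i}: duplicated input source")
            if i in row:
                raise NetworkFormatError(f"node {i}: self-input not allowed")
        if not np.isin(self.tables, (0, 1)).all():
            raise NetworkFormatError("truth-table entries must be 0 or 1")

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.inputs.ravel(), minlength=self.n)

    def n_links(self) -> int:
        return self.n * self.k_in

    def __eq__(self, other):
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.n == other.n
            and self.k_in == other.k_in
            and self.topology == other.topology
            and np.array_equal(self.inputs, other.inputs)
            and np.array_equal(self.tables, other.tables)
        )

    def __hash__(self):
        return hash((self.n, self.k_in, self.inputs.tobytes(), self.tables.tobytes()))


def generate_er_network(
    n: int, k_in: int = 2, bias: float = 0.5, seed: int = 0
) -> BooleanNetwork:
    """Generate a classical random Boolean network with fixed in-degree.

    Each node's ``k_in`` inputs are drawn uniformly without replacement
    from the other ``n - 1`` nodes, and each truth-table entry is 1 with
    probability ``bias`` independently.  ``k_in = 2, bias = 0.5`` is the
    critical regime at the order/chaos boundary.
    """
    _check_basic(n, k_in, bias)
    rng = np.random.default_rng(seed)
    inputs = np.empty((n, k_in), dtype=np.int32)
    for i in range(n):
        pick = rng.choice(n - 1, size=k_in, replace=False)
        # skip over the node itself
        inputs[i] = pick + (pick >= i)
    tables = (rng.random((n, 2 ** k_in)) < bias).astype(np.uint8)
    return BooleanNetwork(
        n=n,
        k_in=k_in,
        inputs=inputs,
        tables=tables,
        topology="erdos_renyi",
        params={"k_in": k_in, "bias": bias, "seed": int(seed)},
    )


def sample_out_degrees(
    law: DegreeLaw, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` independent out-degrees from the truncated power law."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmf = law.pmf(n)
    return rng.choice(len(pmf), size=n, p=pmf).astype(np.int64)


def generate_sf_network(
    n: int,
    k_in: int = 2,
    bias: float = 0.5,
    law: DegreeLaw | None = None,
    seed: int = 0,
    max_resample: int = 10_000,
) -> BooleanNetwork:
    """Generate a Boolean network with scale-free out-degrees.

    Out-degrees are drawn from ``law`` (default: the exponent keyed to
    ``n`` with ``p0 = 0.13``), rejected until they sum to exactly
    ``n * k_in`` so that the link total matches the Erdős–Rényi case.  The
    wiring is then realized configuration-model style: a stub multiset is
    shuffled and dealt ``k_in`` at a time, with local repair swaps to
    remove self-loops and duplicate inputs.
    """
    _check_basic(n, k_in, bias)
    if law is None:
        law = DegreeLaw(gamma=default_gamma(n), p0=0.13)
    rng = np.random.default_rng(seed)
    target = n * k_in

    for attempt in range(1, max_resample + 1):
        degs = sample_out_degrees(law, n, rng)
        if int(degs.sum()) == target:
            break
    else:
        raise GenerationError(
            f"no out-degree sequence summing to {target} in "
            f"{max_resample} attempts",
            attempts=max_resample,
        )

    inputs = _wire_configuration_model(degs, n, k_in, rng)
    tables = (rng.random((n, 2 ** k_in)) < bias).astype(np.uint8)
    return BooleanNetwork(
        n=n,
        k_in=k_in,
        inputs=inputs,
        tables=tables,
        topology="scale_free",
        params={
            "k_in": k_in,
            "bias": bias,
            "gamma": law.gamma,
            "p0": law.p0,
            "k_max": law.resolve_k_max(n),
            "seed": int(seed),
            "degree_attempts": attempt,
        },
    )


def _wire_configuration_model(
    degs: np.ndarray, n: int, k_in: int, rng: np.random.Generator, max_rounds: int = 100
) -> np.ndarray:
    """Deal out-stubs to consumers, repairing self-loops and duplicates.

    Raises :class:`GenerationError` if the sequence cannot be realized
    within ``max_rounds`` shuffle-and-repair rounds.
    """
    stubs = np.repeat(np.arange(n, dtype=np.int32), degs)
    for round_ in range(1, max_rounds + 1):
        rng.shuffle(stubs)
        wiring = stubs.reshape(n, k_in).copy()
        if _repair_wiring(wiring, rng):
            return wiring
    raise GenerationError(
        f"could not realize out-degree sequence without self-loops or "
        f"duplicate inputs in {max_rounds} rounds",
        attempts=max_rounds,
    )


def _repair_wiring(wiring: np.ndarray, rng: np.random.Generator, max_fix: int = 10_000) -> bool:
    """Swap conflicting stubs between rows until every row is valid."""
    n, k_in = wiring.shape

    def bad_positions():
        out = []
        for i in range(n):
            row = wiring[i]
            seen = set()
            for j in range(k_in):
                if row[j] == i or row[j] in seen:
                    out.append((i, j))
                else:
                    seen.add(int(row[j]))
        return out

    for _ in range(max_fix):
        bad = bad_positions()
        if not bad:
            return True
        i, j = bad[rng.integers(len(bad))]
        # swap with a random stub elsewhere
        i2 = int(rng.integers(n))
        j2 = int(rng.integers(k_in))
        if i2 == i:
            continue
        v, v2 = int(wiring[i, j]), int(wiring[i2, j2])
        # the swap must not create a self-loop or duplicate at either end
        if v2 == i or v == i2:
            continue
        if v2 in wiring[i] or v in wiring[i2]:
            continue
        wiring[i, j], wiring[i2, j2] = v2, v
    return False


def _check_basic(n: int, k_in: int, bias: float):
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    if not 1 <= k_in <= n - 1:
        raise ValueError(f"k_in must be in [1, n-1] = [1, {n - 1}], got {k_in}")
    if not 0.0 <= bias <= 1.0:
        raise ValueError(f"bias must be a probability, got {bias}")


# ---------------------------------------------------------------------------
# serialization

def write_network(net: BooleanNetwork, path: str | Path) -> None:
    """Write a network to the JSON interchange format."""
    doc = {
        "n": net.n,
        "k_in": net.k_in,
        "topology": net.topology,
        "params": net.params,
        "nodes": [
            {
                "id": i,
                "inputs": net.inputs[i].tolist(),
                "table": net.tables[i].tolist(),
            }
            for i in range(net.n)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network(path: str | Path) -> BooleanNetwork:
    """Read a network from the JSON interchange format, validating invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise NetworkFormatError(f"not valid JSON: {e}") from e
    for key in ("n", "k_in", "nodes"):
        if key not in doc:
            raise NetworkFormatError(f"missing required field '{key}'")
    n, k_in = doc["n"], doc["k_in"]
    nodes = doc["nodes"]
    if len(nodes) != n:
        raise NetworkFormatError(f"field 'nodes' has {len(nodes)} entries, expected n={n}")
    inputs = np.empty((n, k_in), dtype=np.int32)
    tables = np.empty((n, 2 ** k_in), dtype=np.uint8)
    seen = set()
    for rec in nodes:
        try:
            i = rec["id"]
            ins = rec["inputs"]
            tab = rec["table"]
        except (KeyError, TypeError) as e:
            raise NetworkFormatError(f"node record missing field: {e}") from e
        if not 0 <= i < n or i in seen:
            raise NetworkFormatError(f"bad or duplicate node id {i}")
        seen.add(i)
        if len(ins) != k_in:
            raise NetworkFormatError(
                f"node {i}: field 'inputs' has {len(ins)} entries, expected k_in={k_in}"
            )
        if len(tab) != 2 ** k_in:
            raise NetworkFormatError(
                f"node {i}: field 'table' has {len(tab)} rows, expected {2 ** k_in}"
            )
        inputs[i] = ins
        tables[i] = tab
    return BooleanNetwork(
        n=n,
        k_in=k_in,
        inputs=inputs,
        tables=tables,
        topology=doc.get("topology", "erdos_renyi"),
        params=doc.get("params", {}),
    )


def to_graphml(net: BooleanNetwork, path: str | Path) -> None:
    """Export the wiring (not the rules) as GraphML for inspection."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(net.n))
    for i in range(net.n):
        for src in net.inputs[i]:
            g.add_edge(int(src), i)
    nx.write_graphml(g, str(path))
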