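"""Small seed-deterministic inputs for the test suite, docs and demos."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .network import BooleanNetwork, write_network

__all__ = ["swap_net", "toy_transition_matrix", "figure1_like_matrix", "make_fixture"]


def swap_net() -> BooleanNetwork:
    """Two nodes that copy each other: fixed points (0,0), (1,1) and one 2-cycle."""
    return BooleanNetwork(
        n=2,
        k_in=1,
        inputs=np.array([[1], [0]], dtype=np.int32),
        tables=np.array([[0, 1], [0, 1]], dtype=np.uint8),
        topology="erdos_renyi",
        params={"fixture": "swap_net"},
    )


def toy_transition_matrix(seed: int = 0, m: int = 5, zero_frac: float = 0.5) -> np.ndarray:
    """A random column-stochastic matrix with a dominant diagonal."""
    rng = np.random.default_rng(seed)
    A = rng.random((m, m))
    A[rng.random((m, m)) < zero_frac] = 0.0
    np.fill_diagonal(A, 0.0)
    A = A * 0.3  # keep off-diagonal mass modest
    col = A.sum(axis=0)
    A[np.diag_indices(m)] = 1.0 - col
    return A


def figure1_like_matrix() -> np.ndarray:
    """A hand-sized attractor transition matrix with weights straddling 0.02.

    Mimics the structure of a complete single-flip transition map over a
    handful of attractors: heavy self-returns, a few strong jumps, and a
    sprinkling of rare (< 0.02) transitions that a threshold of 0.02
    prunes away.
    """
    m = 6
    A = np.zeros((m, m))
    strong = {(1, 0): 0.10, (2, 0): 0.05, (3, 2): 0.08, (4, 3): 0.12, (5, 4): 0.06}
    weak = {(0, 1): 0.015, (2, 5): 0.01, (1, 3): 0.005, (5, 2): 0.018}
    for (i, j), w in {**strong, **weak}.items():
        A[i, j] = w
    A[np.diag_indices(m)] = 1.0 - A.sum(axis=0)
    return A


def make_fixture(kind: str, seed: int = 0, outdir: str | Path = ".") -> list[Path]:
    """Write a named fixture to ``outdir`` and return the files created."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    if kind == "tiny_net":
        p = outdir / "tiny_net.json"
        write_network(swap_net(), p)
        files.append(p)
    elif kind == "toy_transition_graph":
        p = outdir / "toy_transition_graph.csv"
        np.savetxt(p, toy_transition_matrix(seed), delimiter=",")
        files.append(p)
    elif kind == "figure1_like":
        p = outdir / "figure1_like.csv"
        np.savetxt(p, figure1_like_matrix(), delimiter=",")
        files.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return files
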