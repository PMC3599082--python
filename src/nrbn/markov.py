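"""Occupation-number dynamics on the attractor transition graph.

In renormalized time (one step per flip) the attractor occupied after a
flip depends only on the attractor occupied before it, so the occupation
probabilities ``P`` evolve by the master equation ``P_{k+1} = A P_k`` with
``A`` the left-stochastic transition matrix.  Restricted to a TES the
chain is irreducible by construction; if additionally every self-return
probability is positive the chain is aperiodic and the occupation vector
converges to the unique stationary distribution ``pi = A pi`` regardless
of the initial condition, at a geometric rate set by the second-largest
eigenvalue modulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil, log
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralReport",
    "ConvergenceError",
    "AmbiguousStationaryError",
    "validate_stochastic",
    "evolve",
    "check_conditions",
    "is_aperiodic_gcd",
    "stationary_power",
    "stationary_eigen",
    "convergence_steps",
    "restrict",
    "stationary_per_tes",
    "read_matrix",
    "write_matrix",
]

MASS_TOL = 1e-12
DEFAULT_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """Power iteration hit its iteration cap; carries the last residual."""

    def __init__(self, iterations: int, residual: float, last: np.ndarray):
        super().__init__(
            f"no convergence in {iterations} iterations (last residual {residual:.3e})"
        )
        self.iterations = iterations
        self.residual = residual
        self.last = last


class AmbiguousStationaryError(ValueError):
    """The eigenvalue-1 eigenspace is not one-dimensional.

    This happens on reducible matrices (several terminal sets): restrict
    the matrix to one TES before asking for its stationary distribution.
    """


def validate_stochastic(A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got shape {A.shape}")
    if A.min() < -tol:
        raise ValueError("matrix has negative entries")
    err = np.abs(A.sum(axis=0) - 1.0).max()
    if err > tol:
        raise ValueError(f"columns must sum to 1 (max deviation {err:.3e})")
    return A


def _as_distribution(P: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (m,):
        raise ValueError(f"occupation vector must have length {m}, got {P.shape}")
    if P.min() < -MASS_TOL:
        raise ValueError("occupation probabilities must be non-negative")
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupation vector must sum to 1, got {P.sum()}")
    return P


def evolve(A: np.ndarray, P: Sequence[float] | np.ndarray, k: int = 1) -> np.ndarray:
    """Apply the master equation ``k`` times; total mass is preserved."""
    A = validate_stochastic(A)
    out = _as_distribution(P, A.shape[0])
    if k < 0:
        raise ValueError("k must be >= 0")
    for _ in range(k):
        out = A @ out
    return out


def check_conditions(A: np.ndarray, members: Sequence[int] | None = None) -> tuple[bool, bool]:
    """(irreducible, aperiodic) for the chain restricted to ``members``.

    Irreducibility is strong connectivity of the restricted positive-entry
    graph.  Aperiodicity here is the sufficient one-step-return condition —
    every restricted diagonal entry positive — which is what guarantees
    uniqueness for TES-restricted matrices; the general gcd test is
    available as :func:`is_aperiodic_gcd`.
    """
    import networkx as nx

    B = restrict(np.asarray(A, dtype=float), members) if members is not None else np.asarray(A, dtype=float)
    dg = nx.from_numpy_array((B.T > 0).astype(int), create_using=nx.DiGraph)
    irreducible = nx.is_strongly_connected(dg)
    aperiodic = bool(np.all(np.diag(B) > 0))
    return irreducible, aperiodic


def is_aperiodic_gcd(A: np.ndarray, members: Sequence[int] | None = None) -> bool:
    """General aperiodicity: gcd of all cycle lengths equals 1."""
    import networkx as nx

    B = restrict(np.asarray(A, dtype=float), members) if members is not None else np.asarray(A, dtype=float)
    dg = nx.from_numpy_array((B.T > 0).astype(int), create_using=nx.DiGraph)
    try:
        return nx.is_aperiodic(dg)
    except nx.NetworkXError:  # graph with no edges
        return False


def restrict(A: np.ndarray, members: Sequence[int] | None) -> np.ndarray:
    """Sub-matrix over ``members``, renormalized to column-stochastic.

    For a genuine TES no probability leaves the set, so renormalization is
    a no-op up to the unresolved-trial bookkeeping.
    """
    if members is None:
        return np.asarray(A, dtype=float)
    idx = np.asarray(sorted(members), dtype=int)
    B = np.asarray(A, dtype=float)[np.ix_(idx, idx)].copy()
    sums = B.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("restriction produced an empty column; not a terminal set")
    return B / sums


def stationary_power(
    A: np.ndarray,
    P0: Sequence[float] | np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = 1_000_000,
) -> tuple[np.ndarray, int]:
    """Stationary distribution by iterating the master equation.

    Iterates until successive occupation vectors differ by less than
    ``tol`` in max-norm.  This is the numerically cheap route for large
    attractor sets; cross-check against :func:`stationary_eigen`.
    """
    A = validate_stochastic(A)
    m = A.shape[0]
    P = np.full(m, 1.0 / m) if P0 is None else _as_distribution(P0, m)
    for it in range(1, max_iter + 1):
        nxt = A @ P
        residual = float(np.abs(nxt - P).max())
        P = nxt
        if residual < tol:
            return P, it
    raise ConvergenceError(max_iter, residual, P)


def stationary_eigen(A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Stationary distribution as the eigenvalue-1 eigenvector.

    Solves the left-stochastic eigenproblem and normalizes the result to
    sum one (the normalization closes the otherwise rank-deficient
    system).  Tiny negative components from floating point are clipped.
    """
    A = validate_stochastic(A)
    vals, vecs = np.linalg.eig(A)
    close = np.isclose(vals, 1.0, atol=1e-8)
    if close.sum() == 0:
        raise AmbiguousStationaryError("no eigenvalue 1 found")
    if close.sum() > 1:
        raise AmbiguousStationaryError(
            f"{close.sum()} unit eigenvalues: the chain is reducible or periodic; "
            "restrict the matrix to a single TES first"
        )
    v = np.real(vecs[:, np.nonzero(close)[0][0]])
    v = v / v.sum()
    if v.min() < -tol:
        raise AmbiguousStationaryError("unit eigenvector has negative components")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


@dataclass
class SpectralReport:
    """Spectral view of convergence toward the stationary distribution."""

    eigenvalues: np.ndarray  # ordered by decreasing modulus
    stationary: np.ndarray
    k_star_empirical: int | None
    k_star_spectral: int | None
    tol: float

    @property
    def spectral_gap_ratio(self) -> float | None:
        """|lambda_2| / |lambda_1|: the geometric decay factor of the error."""
        if len(self.eigenvalues) < 2:
            return None
        return float(abs(self.eigenvalues[1]) / abs(self.eigenvalues[0]))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "eigenvalues": [[float(v.real), float(v.imag)] for v in self.eigenvalues],
            "stationary": self.stationary.tolist(),
            "k_star_empirical": self.k_star_empirical,
            "k_star_spectral": self.k_star_spectral,
            "tol": self.tol,
            "decay_ratio": self.spectral_gap_ratio,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def convergence_steps(
    A: np.ndarray,
    P0: Sequence[float] | np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1_000_000,
) -> SpectralReport:
    """Steps needed for ``P_k`` to reach the stationary vector within ``tol``.

    Reports both the empirical count (iterate and compare against ``pi`` in
    max-norm) and the spectral estimate: expanding ``P0`` over the
    eigenvectors, the error decays like ``|lambda_2|**k`` times the size of
    the initial second-mode coefficient, so
    ``k* ~ log(tol / c2) / log|lambda_2|``.  When ``|lambda_2| = |lambda_1|``
    the spectral estimate is unavailable and only the empirical count is
    returned.
    """
    A = validate_stochastic(A)
    m = A.shape[0]
    P = np.full(m, 1.0 / m) if P0 is None else _as_distribution(P0, m)
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    pi = stationary_eigen(A)

    # empirical count
    k_emp = None
    Pk = P.copy()
    for k in range(max_iter + 1):
        if np.abs(Pk - pi).max() < tol:
            k_emp = k
            break
        Pk = A @ Pk

    # spectral estimate from the initial second-mode coefficient
    k_spec = None
    if m >= 2 and abs(vals[1]) < abs(vals[0]) - 1e-12 and abs(vals[1]) > 0:
        coeffs = np.linalg.solve(vecs, P.astype(complex))
        tail = vecs[:, 1:] * coeffs[1:]
        c2 = float(np.abs(tail.sum(axis=1)).max())
        if c2 <= tol:
            k_spec = 0
        else:
            k_spec = max(0, ceil(log(tol / c2) / log(abs(vals[1]) / abs(vals[0]))))
    return SpectralReport(
        eigenvalues=vals,
        stationary=pi,
        k_star_empirical=k_emp,
        k_star_spectral=k_spec,
        tol=tol,
    )


def stationary_per_tes(A: np.ndarray, decomposition) -> dict[int, np.ndarray]:
    """Stationary distribution of each TES of a decomposition.

    Convenience wrapper for reducible matrices: restricts to each terminal
    set (where uniqueness holds) and returns one vector per TES, indexed by
    position in ``decomposition.tes_list``; each vector is over the TES's
    sorted attractor ids.
    """
    out = {}
    for k, t in enumerate(decomposition.tes_list):
        out[k] = stationary_power(restrict(A, sorted(t.attractor_ids)))[0]
    return out


def write_matrix(A: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csc_matrix

        mmwrite(str(path), csc_matrix(A))
    else:
        np.savetxt(path, A, delimiter=",")


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        return np.asarray(mmread(str(path)).todense())
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
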