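"""Hot loops for synchronous Boolean updating and cycle detection.

The public dynamics API lives in :mod:`nrbn.dynamics`; this module only
holds the per-step update and a Brent cycle-finder, JIT-compiled with
numba when it is available and otherwise run as plain Python/NumPy.
Both paths are exact and return identical results; numba only changes
the speed.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every dynamics test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _step_inplace(inputs, tables, state, out):
    n, k = inputs.shape
    for i in range(n):
        idx = 0
        for j in range(k):
            idx = (idx << 1) | state[inputs[i, j]]
        out[i] = tables[i, idx]


@njit(cache=True)
def _advance(inputs, tables, state, steps):
    cur = state.copy()
    nxt = np.empty_like(cur)
    for _ in range(steps):
        _step_inplace(inputs, tables, cur, nxt)
        cur, nxt = nxt, cur
    return cur


@njit(cache=True)
def _states_equal(a, b):
    for i in range(a.shape[0]):
        if a[i] != b[i]:
            return False
    return True


@njit(cache=True)
def _brent(inputs, tables, x0, max_steps):
    """Brent's cycle detection on the synchronous update map.

    Returns ``(mu, lam)`` — transient length and cycle period — or
    ``(-1, -1)`` if ``mu + lam`` would exceed ``max_steps``.
    """
    power = 1
    lam = 1
    tortoise = x0.copy()
    hare = x0.copy()
    tmp = np.empty_like(x0)
    _step_inplace(inputs, tables, tortoise, hare)
    steps = 1
    while not _states_equal(tortoise, hare):
        if power == lam:
            tortoise[:] = hare
            power *= 2
            lam = 0
        _step_inplace(inputs, tables, hare, tmp)
        hare, tmp = tmp, hare
        lam += 1
        steps += 1
        if steps > 3 * max_steps + 4:
            return -1, -1
    # find mu: advance hare lam steps ahead of x0, then move in lockstep
    tortoise[:] = x0
    hare[:] = x0
    for _ in range(lam):
        _step_inplace(inputs, tables, hare, tmp)
        hare, tmp = tmp, hare
    mu = 0
    while not _states_equal(tortoise, hare):
        _step_inplace(inputs, tables, tortoise, tmp)
        tortoise, tmp = tmp, tortoise
        _step_inplace(inputs, tables, hare, tmp)
        hare, tmp = tmp, hare
        mu += 1
        if mu > max_steps:
            return -1, -1
    if mu + lam > max_steps:
        return -1, -1
    return mu, lam


@njit(cache=True)
def _collect_cycle(inputs, tables, x0, mu, lam):
    """States of the cycle reached from ``x0``, starting at phase ``mu``."""
    cur = _advance(inputs, tables, x0, mu)
    n = cur.shape[0]
    out = np.empty((lam, n), dtype=np.uint8)
    nxt = np.empty_like(cur)
    for t in range(lam):
        out[t] = cur
        _step_inplace(inputs, tables, cur, nxt)
        cur, nxt = nxt, cur
    return out


def step_array(inputs, tables, state):
    """One synchronous update of ``state`` (vector in, vector out)."""
    out = np.empty_like(state)
    _step_inplace(inputs, tables, state, out)
    return out


def step_many(inputs, tables, states):
    """Vectorized synchronous update of a batch of states (m, n)."""
    n, k = inputs.shape
    idx = np.zeros(states.shape[:-1] + (n,), dtype=np.int64)
    for j in range(k):
        idx = (idx << 1) | states[..., inputs[:, j]]
    return tables[np.arange(n), idx].astype(np.uint8)


def find_cycle(inputs, tables, x0, max_steps):
    """Transient length, period and cycle states from ``x0``.

    Returns ``(mu, lam, cycle)`` or ``(None, None, None)`` when the
    attractor is not reached within ``max_steps`` total steps.
    """
    mu, lam = _brent(inputs, tables, x0, max_steps)
    if mu < 0:
        return None, None, None
    cycle = _collect_cycle(inputs, tables, x0, mu, lam)
    return int(mu), int(lam), np.asarray(cycle)
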