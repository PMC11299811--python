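"""Numba kernels for the bounded random walk.

Two variants of the first-passage loop exist:

* :func:`walk_first_passage` draws fresh standard normals from numba's
  global RNG (seeded per call).  This is the reference generative path used
  by the public simulators.
* :func:`walk_first_passage_pool` reads pre-generated increments from a
  shared noise pool at per-trial offsets.  The fitting objective uses it so
  that every candidate parameter vector is evaluated on *common random
  numbers*: the objective surface is then deterministic and smooth enough
  for differential evolution, and a single evaluation costs milliseconds.

Both return, per trial, the signed choice (+1/-1, 0 when the walk was
censored at ``max_steps``) and the number of accumulation steps taken.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["walk_first_passage", "walk_first_passage_pool"]


@njit(cache=True)
def walk_first_passage(v_tau, start, a, noise_scale, max_steps, seed):
    """Simulate bounded random walks with fresh Gaussian increments.

    v_tau : per-trial signed drift increment (v * tau).
    start : common starting evidence (z * a).
    noise_scale : sigma * sqrt(tau).
    """
    n = v_tau.shape[0]
    np.random.seed(seed)
    choice = np.zeros(n, np.int8)
    steps = np.empty(n, np.int64)
    for i in range(n):
        e = start
        s = 0
        c = np.int8(0)
        while s < max_steps:
            s += 1
            e += v_tau[i] + noise_scale * np.random.standard_normal()
            if e >= a:
                c = np.int8(1)
                break
            if e <= -a:
                c = np.int8(-1)
                break
        if c == 0 and e > 0:
            c = np.int8(2)  # censored, currently positive
        elif c == 0:
            c = np.int8(-2)  # censored, currently negative or zero
        choice[i] = c
        steps[i] = s
    return choice, steps


@njit(cache=True)
def walk_first_passage_pool(v_tau, start, a, pool, offsets, max_steps):
    """Same walk, but increments come from ``pool`` (already scaled by
    sigma * sqrt(tau)), read sequentially from ``offsets[i]`` with
    wrap-around.  Fully deterministic given the pool and offsets."""
    n = v_tau.shape[0]
    m = pool.shape[0]
    choice = np.zeros(n, np.int8)
    steps = np.empty(n, np.int64)
    for i in range(n):
        e = start
        s = 0
        c = np.int8(0)
        j = offsets[i]
        while s < max_steps:
            s += 1
            e += v_tau[i] + pool[j]
            j += 1
            if j == m:
                j = 0
            if e >= a:
                c = np.int8(1)
                break
            if e <= -a:
                c = np.int8(-1)
                break
        if c == 0 and e > 0:
            c = np.int8(2)
        elif c == 0:
            c = np.int8(-2)
        choice[i] = c
        steps[i] = s
    return choice, steps
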