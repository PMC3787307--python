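"""JIT-compiled inner loops for the expectancy-valence likelihood and simulator.

These kernels are the hot path of maximum-likelihood fitting (hundreds of
thousands of likelihood evaluations per cohort); everything user-facing
lives in :mod:`igtev.model`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

THETA_POW3 = 0
THETA_TRIAL_POW = 1


@njit(cache=True)
def _theta(c: float, t: int, variant: int) -> float:
    if variant == THETA_POW3:
        return 3.0 ** c - 1.0
    return (t / 10.0) ** c


@njit(cache=True)
def negative_log_likelihood(
    w: float,
    phi: float,
    c: float,
    chosen: np.ndarray,
    win: np.ndarray,
    loss: np.ndarray,
    variant: int,
    prob_floor: float,
) -> float:
    """Negative one-step-ahead log-likelihood of a session under (w, phi, c).

    Expectancies start at zero (uniform first choice); only the chosen
    deck's expectancy is updated, with the trial's valence. Choice
    probabilities use the softmax/Luce rule with max-subtraction and are
    floored at ``prob_floor`` before the log.
    """
    n = chosen.shape[0]
    E = np.zeros(4)
    total = 0.0
    for t in range(n):
        th = _theta(c, t + 1, variant)
        m = th * E[0]
        for j in range(1, 4):
            if th * E[j] > m:
                m = th * E[j]
        denom = 0.0
        for j in range(4):
            denom += math.exp(th * E[j] - m)
        p = math.exp(th * E[chosen[t]] - m) / denom
        if p < prob_floor:
            p = prob_floor
        total += math.log(p)
        v = w * win[t] - (1.0 - w) * loss[t]
        E[chosen[t]] += phi * (v - E[chosen[t]])
    return -total


@njit(cache=True)
def simulate_choices(
    w: float,
    phi: float,
    c: float,
    n_trials: int,
    gains: np.ndarray,
    loss_cycles: np.ndarray,
    uniforms: np.ndarray,
    variant: int,
):
    """Generate a session from the model; randomness enters only via ``uniforms``.

    ``gains`` is the per-deck gain (length 4); ``loss_cycles`` the 4x10 loss
    schedule. Returns (chosen deck index, win, loss) arrays.
    """
    E = np.zeros(4)
    positions = np.zeros(4, dtype=np.int64)
    chosen = np.empty(n_trials, dtype=np.int64)
    win = np.empty(n_trials)
    loss = np.empty(n_trials)
    for t in range(n_trials):
        th = _theta(c, t + 1, variant)
        m = th * E[0]
        for j in range(1, 4):
            if th * E[j] > m:
                m = th * E[j]
        denom = 0.0
        p = np.empty(4)
        for j in range(4):
            p[j] = math.exp(th * E[j] - m)
            denom += p[j]
        u = uniforms[t] * denom
        acc = 0.0
        j_sel = 3
        for j in range(4):
            acc += p[j]
            if u <= acc:
                j_sel = j
                break
        chosen[t] = j_sel
        win[t] = gains[j_sel]
        loss[t] = loss_cycles[j_sel, positions[j_sel] % 10]
        positions[j_sel] += 1
        v = w * win[t] - (1.0 - w) * loss[t]
        E[j_sel] += phi * (v - E[j_sel])
    return chosen, win, loss
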