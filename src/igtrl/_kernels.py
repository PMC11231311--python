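"""Compiled trial-loop kernels for the choice-model likelihoods.

Parameters arrive as a dense 8-vector laid out
``[A, alpha, cons, lambda, epP, epN, K, w]``; the PVL variants read
only the first four slots.  Model ids: 0 = VPP, 1 = PVL-Delta,
2 = PVL-DecayRI.  Net outcomes are already rescaled by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_VPP = 0
MODEL_PVL_DELTA = 1
MODEL_PVL_DECAY = 2


@njit(cache=False)
def loglik_trials(choices, nets, params, model_id):  # pragma: no cover - thin numba shim
    """Per-trial log-probability of the observed choices.

    choices : int64[T] deck indices 0..3
    nets    : float64[T] rescaled net outcomes
    params  : float64[8]
    """
    T = choices.shape[0]
    out = np.empty(T, dtype=np.float64)
    A = params[0]
    alpha = params[1]
    cons = params[2]
    lam = params[3]
    epP = params[4]
    epN = params[5]
    K = params[6]
    w = params[7]
    theta = 3.0 ** cons - 1.0

    E = np.zeros(4, dtype=np.float64)
    P = np.zeros(4, dtype=np.float64)
    z = np.empty(4, dtype=np.float64)
    for t in range(T):
        c = choices[t]
        # value of each deck entering the softmax
        if model_id == MODEL_VPP:
            for j in range(4):
                z[j] = theta * (w * E[j] + (1.0 - w) * P[j])
        else:
            for j in range(4):
                z[j] = theta * E[j]
        m = z[0]
        for j in range(1, 4):
            if z[j] > m:
                m = z[j]
        s = 0.0
        for j in range(4):
            s += np.exp(z[j] - m)
        out[t] = z[c] - m - np.log(s)

        # prospect-valence utility of the realized net outcome
        x = nets[t]
        if x >= 0.0:
            u = x ** alpha
        else:
            u = -lam * (-x) ** alpha

        # expectancy update
        if model_id == MODEL_PVL_DECAY:
            for j in range(4):
                E[j] = A * E[j]
            E[c] = E[c] + u
        else:
            E[c] = E[c] + A * (u - E[c])

        # perseverance update (VPP only)
        if model_id == MODEL_VPP:
            for j in range(4):
                P[j] = K * P[j]
            if x >= 0.0:
                P[c] = P[c] + epP
            else:
                P[c] = P[c] + epN
    return out


@njit(cache=False)
def loglik_batch(choices, nets, params, model_id):  # pragma: no cover - thin numba shim
    """Batched per-trial log-probabilities.

    choices : int64[B, T]; nets : float64[B, T]; params : float64[B, 8]
    Returns float64[B, T].
    """
    B, T = choices.shape
    out = np.empty((B, T), dtype=np.float64)
    for b in range(B):
        out[b] = loglik_trials(choices[b], nets[b], params[b], model_id)
    return out
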