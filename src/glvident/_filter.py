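"""Numba kernels for the bootstrap particle filter.

The filter propagates particles through the gLV SDE by Euler-Maruyama and
weights them by a multinomial read-count likelihood at each observation.
These inner loops dominate the cost of particle MCMC (millions of Euler
steps per chain), hence the compiled implementation; the public API lives in
:mod:`glvident.inference`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Positivity floor, mirroring glvident.synthetic: multiplicative noise cannot
# reach zero in continuous time, so undershoots are clamped to a tiny
# fraction of the community total (keeps multinomial log-probabilities
# finite).
_FLOOR_FRACTION = 1e-10


@njit(cache=False)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=False)
def _systematic_resample(weights, u):
    """Systematic resampling: one uniform u in [0,1), stratified positions."""
    P = weights.shape[0]
    positions = (u + np.arange(P)) / P
    cumsum = np.cumsum(weights)
    cumsum[P - 1] = 1.0  # guard against roundoff
    indexes = np.empty(P, dtype=np.int64)
    i = 0
    j = 0
    while i < P:
        if positions[i] < cumsum[j]:
            indexes[i] = j
            i += 1
        else:
            j += 1
    return indexes


@njit(cache=False)
def _propagate(states, r, B, sigma, dt, n_steps):
    """Euler-Maruyama steps for all particles in place."""
    P, n = states.shape
    sqrt_dt = math.sqrt(dt)
    new = np.empty(n)
    for _ in range(n_steps):
        for p in range(P):
            total = 0.0
            for i in range(n):
                interact = 0.0
                for j in range(n):
                    interact += B[i, j] * states[p, j]
                drift = states[p, i] * (r[i] + interact)
                dW = np.random.normal(0.0, 1.0) * sqrt_dt
                new[i] = states[p, i] + drift * dt + sigma[i] * states[p, i] * dW
                total += new[i] if new[i] > 0.0 else 0.0
            floor = _FLOOR_FRACTION * total
            for i in range(n):
                states[p, i] = new[i] if new[i] > floor else floor


@njit(cache=False)
def bootstrap_filter(counts, log_coeffs, obs_steps, init_state, r, B, sigma, dt,
                     n_particles, seed):
    """Log-likelihood estimate of read counts under the gLV state-space model.

    Parameters
    ----------
    counts : (T, n) int64
        Observed read counts (rows sum to the depth V).
    log_coeffs : (T,) float64
        Multinomial log coefficient log(V!) - sum_i log(c_i!) per sample,
        precomputed by the caller.
    obs_steps : (T,) int64
        Euler steps from the trajectory start to each observation.
    init_state : (n,) float64
        Latent state at the first observation time (all particles start
        here; the first observation then contributes a constant weight).
    seed : int64
        Seed for the kernel's random stream.

    Returns
    -------
    (loglik, collapsed) : (float64, bool)
        ``collapsed`` flags a step where every particle had zero weight, in
        which case ``loglik`` is -inf.
    """
    _seed_numba(seed)
    T, n = counts.shape
    P = n_particles
    states = np.empty((P, n))
    for p in range(P):
        for i in range(n):
            states[p, i] = init_state[i]

    loglik = 0.0
    logw = np.empty(P)
    for t in range(T):
        if t > 0:
            _propagate(states, r, B, sigma, dt, obs_steps[t] - obs_steps[t - 1])
        # multinomial log-weights at the particle compositions
        maxw = -np.inf
        for p in range(P):
            total = 0.0
            for i in range(n):
                total += states[p, i]
            lw = log_coeffs[t]
            if total <= 0.0:
                lw = -np.inf
            else:
                for i in range(n):
                    c = counts[t, i]
                    if c > 0:
                        prop = states[p, i] / total
                        if prop <= 0.0:
                            lw = -np.inf
                            break
                        lw += c * math.log(prop)
            logw[p] = lw
            if lw > maxw:
                maxw = lw
        if maxw == -np.inf:
            return -np.inf, True
        sumw = 0.0
        for p in range(P):
            logw[p] = math.exp(logw[p] - maxw)
            sumw += logw[p]
        loglik += maxw + math.log(sumw / P)
        # systematic resample (skip when all weights equal, e.g. t == 0)
        weights = logw / sumw
        u = np.random.random()
        idx = _systematic_resample(weights, u)
        states = states[idx].copy()
    return loglik, False
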