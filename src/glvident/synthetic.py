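"""Synthetic community time series: process noise and sequencing noise.

Two noise layers sit between the deterministic gLV dynamics and the data a
sequencing study actually sees:

* **Process (environmental) noise** — the latent abundances follow the Ito
  SDE ``dN_i = N_i (r_i + sum_j B[i,j] N_j) dt + sigma_i N_i dW_i`` with
  independent Wiener processes, integrated by Euler-Maruyama at a fixed step
  ``dt``.  Both drift and diffusion are proportional to N_i, so the SDE is
  equivariant under the B-scale gauge: (r, cB, X0/c) driven by the same
  Wiener increments gives exactly 1/c times the (r, B, X0) paths, hence
  identical compositions.

* **Measurement (sequencing) noise** — per sample either Dirichlet-distributed
  proportions with concentrations ``alpha_i = V * Ntilde_i / sum_j Ntilde_j``
  (the concentrations sum to the read depth V, so V controls the error
  magnitude), or multinomial read counts of total depth V at the latent
  proportions.  The two emissions share first moments; the multinomial one is
  the default fitting target because the inference likelihood is multinomial.

The three-species benchmark community (two gauge-equivalent parameter sets,
one 100x the other) is bundled by :func:`make_benchmark_dataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import DegenerateSampleError, DimensionError
from .model import (
    DEFAULT_TIMES,
    AbundanceTrajectory,
    CompositionTrajectory,
    GLVParameters,
    _check_times,
)

__all__ = [
    "NoiseModel",
    "ObservedCounts",
    "simulate_sde",
    "observe_dirichlet",
    "observe_counts",
    "make_benchmark_dataset",
    "benchmark_parameters",
    "benchmark_initial_state",
]

# Positivity floor for Euler-Maruyama: multiplicative noise cannot reach 0 in
# continuous time, so undershoots are discretization artifacts.  A species is
# clamped at FLOOR_FRACTION x current community total; if it sits on the floor
# for FLOOR_ABSORB_STEPS consecutive steps it is absorbed at exactly 0.
FLOOR_FRACTION = 1e-10
FLOOR_ABSORB_STEPS = 5


@dataclass(frozen=True)
class NoiseModel:
    """Noise settings shared by the process and measurement layers.

    Parameters
    ----------
    sigma : array-like
        Per-species environmental noise scales (1/sqrt(time)), >= 0.
    dt : float
        Euler-Maruyama step; observation times are snapped to this grid.
    V : int
        Read depth per sample — the Dirichlet concentration total and the
        multinomial number of trials.
    seed : int, optional
        Seed for all stochastic draws made with this model; ``None`` draws
        fresh entropy.
    """

    sigma: np.ndarray
    dt: float = 0.001
    V: int = 500
    seed: int | None = None

    def __post_init__(self):
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sigma < 0):
            raise DimensionError("sigma entries must be >= 0")
        if self.dt <= 0:
            raise DimensionError("dt must be positive")
        if self.V <= 0:
            raise DimensionError("V must be positive")
        object.__setattr__(self, "sigma", sigma)

    def rng(self, seed: int | None = None) -> np.random.Generator:
        if seed is None:
            seed = self.seed
        return np.random.default_rng(seed)


@dataclass(frozen=True)
class ObservedCounts:
    """Read counts per taxon per sample; every row sums to its depth."""

    times: np.ndarray
    counts: np.ndarray
    depth: int

    def __post_init__(self):
        times = _check_times(self.times)
        counts = np.atleast_2d(np.asarray(self.counts))
        if not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.round(counts)):
                raise DimensionError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.shape[0] != times.size:
            raise DimensionError("counts rows must match times")
        if np.any(counts < 0):
            raise DimensionError("counts must be nonnegative")
        if np.any(counts.sum(axis=1) != self.depth):
            raise DimensionError(f"every counts row must sum to depth {self.depth}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.depth


def _snap_to_grid(times: np.ndarray, t0: float, dt: float) -> np.ndarray:
    """Snap observation times to the Euler grid, warning when they move."""
    steps = np.round((times - t0) / dt).astype(np.int64)
    snapped = t0 + steps * dt
    if np.max(np.abs(snapped - times)) > 1e-9 * max(1.0, dt):
        warnings.warn(
            "observation times snapped to the Euler-Maruyama dt grid",
            stacklevel=3,
        )
    return steps


def simulate_sde(
    params: GLVParameters,
    initial_abundances: np.ndarray,
    noise: NoiseModel,
    times: np.ndarray,
    rng: np.random.Generator | None = None,
) -> AbundanceTrajectory:
    """Euler-Maruyama path of the gLV SDE recorded at the requested times.

    With ``sigma = 0`` this reduces to fixed-step deterministic Euler
    integration (discretization error O(dt)).  Gaussian increments have
    variance ``dt`` per species and step, independent across species.
    """
    times = _check_times(times)
    x0 = np.asarray(initial_abundances, dtype=float)
    n = params.n_species
    if x0.shape != (n,):
        raise DimensionError("initial_abundances has wrong length")
    if np.any(x0 <= 0):
        raise DimensionError("SDE simulation requires strictly positive start")
    sigma = np.broadcast_to(noise.sigma, (n,))
    if rng is None:
        rng = noise.rng()

    dt = noise.dt
    sqrt_dt = np.sqrt(dt)
    obs_steps = _snap_to_grid(times, times[0], dt)
    out = np.empty((times.size, n))
    state = x0.copy()
    out[0] = state
    floor_run = np.zeros(n, dtype=int)
    step = 0
    for k in range(1, times.size):
        while step < obs_steps[k]:
            drift = state * (params.r + params.B @ state)
            diffusion = sigma * state
            dW = rng.standard_normal(n) * sqrt_dt
            state = state + drift * dt + diffusion * dW
            floor = FLOOR_FRACTION * max(state.sum(), 0.0)
            below = state < floor
            if np.any(below):
                floor_run[below] += 1
                floor_run[~below] = 0
                absorbed = below & (floor_run >= FLOOR_ABSORB_STEPS)
                state[below] = floor
                state[absorbed] = 0.0
                if np.any(absorbed):
                    warnings.warn(
                        f"species {np.flatnonzero(absorbed).tolist()} absorbed at 0 "
                        f"near t={times[0] + (step + 1) * dt:.4g}",
                        stacklevel=2,
                    )
            else:
                floor_run[:] = 0
            step += 1
        out[k] = state
    return AbundanceTrajectory(times, out, kind="stochastic")


def _latent_proportions(latent: AbundanceTrajectory) -> np.ndarray:
    totals = latent.totals
    if np.any(totals <= 0):
        raise DegenerateSampleError("latent trajectory has a zero-total sample")
    return latent.abundances / totals[:, None]


def observe_dirichlet(
    latent: AbundanceTrajectory,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> CompositionTrajectory:
    """Dirichlet-distributed observed proportions, one draw per sample.

    Concentrations are ``alpha_i = V * Ntilde_i / sum_j Ntilde_j`` — they sum
    to V, so larger read depth concentrates the draw on the latent
    composition (variance p_i (1 - p_i) / (V + 1) per component).
    """
    if rng is None:
        rng = noise.rng()
    alphas = noise.V * _latent_proportions(latent)
    drawn = np.vstack([rng.dirichlet(a) for a in alphas])
    return CompositionTrajectory(latent.times, drawn)


def observe_counts(
    latent: AbundanceTrajectory,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> ObservedCounts:
    """Multinomial read counts: V reads split by the latent proportions."""
    if rng is None:
        rng = noise.rng()
    props = _latent_proportions(latent)
    counts = np.vstack([rng.multinomial(noise.V, p) for p in props])
    return ObservedCounts(latent.times, counts, depth=noise.V)


# --------------------------------------------------------------------------
# Three-species benchmark community.
#
# Two parameter sets related by the scale gauge (set 2 = 100 x set 1 in B,
# 1/100 in initial abundances) — they generate identical composition
# trajectories.  The repeating decimals are exact: B22 = -2/75 = -0.0266...,
# B33 = -2/135 = -0.0148148...
_BENCH_R = (6.0, 4.0, 2.0)
_BENCH_B1 = (
    (Fraction(-5, 100), Fraction(15, 100), Fraction(-20, 100)),
    (Fraction(-1, 100), Fraction(-2, 75), Fraction(5, 100)),
    (Fraction(10, 100), Fraction(-10, 100), Fraction(-2, 135)),
)
_BENCH_X0_1 = (10.0, 14.0, 4.0)
_BENCH_SIGMA = 0.1


def benchmark_parameters(value_set: int = 2) -> GLVParameters:
    """The benchmark three-species gLV parameters (value set 1 or 2)."""
    if value_set not in (1, 2):
        raise ValueError("value_set must be 1 or 2")
    scale = 1.0 if value_set == 1 else 100.0
    B = np.array([[float(b) * scale for b in row] for row in _BENCH_B1])
    return GLVParameters(np.array(_BENCH_R), B)


def benchmark_initial_state(value_set: int = 2, scenario: str = "standard") -> np.ndarray:
    """Initial abundances for the benchmark community.

    ``standard`` uses the value-set totals (N(0) = 28 for set 1, 0.28 for
    set 2); ``unit_N0`` rescales to total abundance 1 while keeping the
    10:14:4 composition.
    """
    x0 = np.array(_BENCH_X0_1)
    if value_set == 2:
        x0 = x0 / 100.0
    elif value_set != 1:
        raise ValueError("value_set must be 1 or 2")
    if scenario == "standard":
        return x0
    if scenario == "unit_N0":
        return x0 / x0.sum()
    raise ValueError("scenario must be 'standard' or 'unit_N0'")


def make_benchmark_dataset(
    value_set: int = 2,
    scenario: str = "standard",
    seed: int | None = 0,
    times: np.ndarray | None = None,
    emission: str = "counts",
):
    """Generate one complete synthetic dataset for the benchmark community.

    Simulates the latent SDE (sigma_i = 0.1, dt = 0.001) on the default
    51-point grid over t in [0, 5] and emits sequencing observations at depth
    V = 500.

    Parameters
    ----------
    emission : {"counts", "dirichlet"}
        ``"counts"`` (default) draws multinomial read counts — the likelihood
        used for fitting is multinomial, so this is the matched emission.
        ``"dirichlet"`` returns the Dirichlet proportions instead.

    Returns
    -------
    (latent, observed, params) : tuple
        Latent :class:`AbundanceTrajectory`, the observation
        (:class:`ObservedCounts` or :class:`CompositionTrajectory`), and the
        true :class:`GLVParameters`.
    """
    params = benchmark_parameters(value_set)
    x0 = benchmark_initial_state(value_set, scenario)
    if times is None:
        times = DEFAULT_TIMES
    noise = NoiseModel(
        sigma=np.full(3, _BENCH_SIGMA), dt=0.001, V=500, seed=seed
    )
    rng = noise.rng()
    latent = simulate_sde(params, x0, noise, times, rng=rng)
    if emission == "counts":
        observed = observe_counts(latent, noise, rng=rng)
    elif emission == "dirichlet":
        observed = observe_dirichlet(latent, noise, rng=rng)
    else:
        raise ValueError("emission must be 'counts' or 'dirichlet'")
    return latent, observed, params
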