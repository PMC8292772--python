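"""Core generalized Lotka-Volterra (gLV) model and its compositional form.

The gLV model tracks absolute abundances N_i of an n-species community,

    dN_i/dt = N_i (r_i + sum_j B[i, j] N_j),

with per-capita growth rates ``r`` and interaction matrix ``B`` (entry
``B[i, j]`` is the effect of species j on the per-capita growth of species i).
Sequencing data, however, observe only the composition x_i = N_i / N with
N = sum_i N_i.  This module provides the exact reformulation of the dynamics
in terms of (x, N), deterministic integration, projection onto the simplex,
and — for two species — closed-form reconstruction of the total abundance
N(t) from the composition and its derivative.

A central fact used throughout: rescaling B -> c*B while rescaling initial
abundances by 1/c leaves the composition trajectory x(t) unchanged, which is
why interaction rates are only identifiable up to a common scale from
relative-abundance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    DegenerateSampleError,
    DimensionError,
    IntegrationError,
    SingularReconstructionError,
    UndefinedCarryingCapacityError,
)

__all__ = [
    "GLVParameters",
    "AbundanceTrajectory",
    "CompositionTrajectory",
    "glv_rhs",
    "carrying_capacity",
    "solve_deterministic",
    "to_composition",
    "compositional_rhs",
    "reconstruct_total",
    "DEFAULT_TIMES",
]

#: Default observation grid: 51 evenly spaced samples on t in [0, 5].  This
#: covers the transient (which carries the interaction information) plus the
#: approach to equilibrium for the benchmark three-species community.
DEFAULT_TIMES = np.linspace(0.0, 5.0, 51)

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class GLVParameters:
    """Growth rates and interaction matrix of one gLV system.

    Parameters
    ----------
    r : array-like, shape (n,)
        Per-capita growth rates (1/time).
    B : array-like, shape (n, n)
        Interaction matrix (1/(abundance*time)); ``B[i, j]`` is the effect of
        species j on the per-capita growth rate of species i.  No sign
        constraint is enforced: negative diagonals give positive carrying
        capacities but are not required for identifiability analysis.
    """

    r: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if r.ndim != 1:
            raise DimensionError("r must be a 1-d vector")
        n = r.shape[0]
        if B.shape != (n, n):
            raise DimensionError(f"B must be ({n}, {n}), got {B.shape}")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(B))):
            raise DimensionError("r and B entries must be finite")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "B", B)

    @property
    def n_species(self) -> int:
        return self.r.shape[0]

    def scaled(self, c: float) -> "GLVParameters":
        """Return the gauge-equivalent system (r, c*B)."""
        return GLVParameters(self.r.copy(), c * self.B)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise DimensionError("times must be a non-empty 1-d vector")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DimensionError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class AbundanceTrajectory:
    """Latent absolute-abundance time series (one row per time)."""

    times: np.ndarray
    abundances: np.ndarray
    kind: str = "deterministic"  # "deterministic" | "stochastic"

    def __post_init__(self):
        times = _check_times(self.times)
        ab = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        if ab.shape[0] != times.size:
            raise DimensionError(
                f"abundances has {ab.shape[0]} rows but times has {times.size}"
            )
        if np.any(ab < 0):
            raise DimensionError("abundances must be nonnegative")
        if self.kind not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "abundances", ab)

    @property
    def n_species(self) -> int:
        return self.abundances.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.abundances.sum(axis=1)


@dataclass(frozen=True)
class CompositionTrajectory:
    """Relative-abundance time series; rows lie on the unit simplex.

    ``total_abundance`` is optional and present only when the total N(t) is
    known (e.g. carried along from an absolute simulation) or reconstructed.
    """

    times: np.ndarray
    proportions: np.ndarray
    total_abundance: np.ndarray | None = field(default=None)

    def __post_init__(self):
        times = _check_times(self.times)
        p = np.atleast_2d(np.asarray(self.proportions, dtype=float))
        if p.shape[0] != times.size:
            raise DimensionError(
                f"proportions has {p.shape[0]} rows but times has {times.size}"
            )
        if np.any(p < -_SIMPLEX_TOL) or np.any(p > 1 + _SIMPLEX_TOL):
            raise DimensionError("proportions must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > _SIMPLEX_TOL):
            raise DimensionError("each proportions row must sum to 1 (tol 1e-9)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "proportions", p)
        if self.total_abundance is not None:
            N = np.asarray(self.total_abundance, dtype=float)
            if N.shape != times.shape:
                raise DimensionError("total_abundance must match times")
            object.__setattr__(self, "total_abundance", N)

    @property
    def n_species(self) -> int:
        return self.proportions.shape[1]


def glv_rhs(state: np.ndarray, params: GLVParameters) -> np.ndarray:
    """Time derivative dN/dt of the gLV system at ``state``.

    Implements dN_i/dt = N_i (r_i + sum_j B[i, j] N_j).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_species,):
        raise DimensionError(
            f"state must have shape ({params.n_species},), got {state.shape}"
        )
    if not np.all(np.isfinite(state)):
        raise DimensionError("state entries must be finite")
    return state * (params.r + params.B @ state)


def carrying_capacity(params: GLVParameters) -> np.ndarray:
    """Single-species equilibria K_i = -r_i / B[i, i].

    Raises
    ------
    UndefinedCarryingCapacityError
        If any diagonal entry of B is zero; the offending species indices are
        attached to the exception.
    """
    diag = np.diag(params.B)
    bad = np.flatnonzero(diag == 0)
    if bad.size:
        raise UndefinedCarryingCapacityError(bad)
    return -params.r / diag


def solve_deterministic(
    params: GLVParameters,
    initial_abundances: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> AbundanceTrajectory:
    """Integrate the deterministic gLV ODE at the requested times.

    Uses a stiff-capable adaptive integrator (LSODA).  The gLV flow preserves
    nonnegativity from a nonnegative start, so no clipping is applied.
    """
    times = _check_times(times)
    x0 = np.asarray(initial_abundances, dtype=float)
    if x0.shape != (params.n_species,):
        raise DimensionError("initial_abundances has wrong length")
    if np.any(x0 < 0):
        raise DimensionError("initial abundances must be nonnegative")
    if times.size == 1:
        return AbundanceTrajectory(times, x0[None, :], kind="deterministic")

    sol = solve_ivp(
        lambda t, y: y * (params.r + params.B @ y),
        (times[0], times[-1]),
        x0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else times[0]
        raise IntegrationError(f"gLV integration failed: {sol.message}", last)
    # LSODA can undershoot 0 by roundoff near extinction; snap tiny negatives.
    y = sol.y.T
    y[(y < 0) & (y > -atol * 10)] = 0.0
    return AbundanceTrajectory(times, y, kind="deterministic")


def to_composition(traj: AbundanceTrajectory) -> CompositionTrajectory:
    """Project an absolute trajectory onto the simplex: x = N_i / N.

    The row totals are carried along as ``total_abundance``.
    """
    totals = traj.totals
    if np.any(totals <= 0):
        bad = traj.times[totals <= 0]
        raise DegenerateSampleError(
            f"zero total abundance at times {bad.tolist()}; cannot normalize"
        )
    return CompositionTrajectory(
        traj.times, traj.abundances / totals[:, None], total_abundance=totals
    )


def compositional_rhs(
    x: np.ndarray, N: float, params: GLVParameters
) -> tuple[np.ndarray, float]:
    """Exact (dx/dt, dN/dt) of the composition/total reformulation.

    Obtained from the quotient rule applied to x_i = N_i / N:

        dx_i/dt = x_i [ (r_i - sum_j r_j x_j)
                        + N (sum_j B[i,j] x_j - sum_{k,j} x_k B[k,j] x_j) ]
        dN/dt   = N sum_j x_j (r_j + N sum_k B[j,k] x_k)

    The components of dx/dt sum to zero identically (the flow stays on the
    simplex); for two species this is the familiar y' = -x'.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_species,):
        raise DimensionError("x has wrong length")
    if abs(x.sum() - 1.0) > 1e-6 or np.any(x < -1e-6):
        raise DimensionError("x must lie on the unit simplex")
    if N <= 0:
        raise DimensionError("N must be positive")
    percap = params.r + N * (params.B @ x)  # per-capita growth of each species
    mean_percap = x @ percap
    dx = x * (percap - mean_percap)
    dN = N * mean_percap
    return dx, float(dN)


def reconstruct_total(
    comp: CompositionTrajectory,
    params: GLVParameters,
    x_derivative: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Recover N(t) for a two-species system from its composition alone.

    Solving the composition equation x' = x(1-x)[(r1-r2) + N ((B11-B21) x +
    (B12-B22)(1-x))] for N gives

        N = [ (r1-r2)(x-1)x + x' ]
            / [ (x-1)x (B22 + B12 (x-1) - (B11 - B21 + B22) x) ].

    This is homogeneous of degree -1 in B: scaling B by c scales the
    reconstructed N by 1/c — the same scale gauge that makes absolute
    abundance unrecoverable without an anchor measurement.

    Parameters
    ----------
    x_derivative : optional
        dx/dt of the first species at each time.  When omitted and the
        trajectory carries a ``total_abundance`` track, x' is computed
        analytically from :func:`compositional_rhs`; otherwise centered
        finite differences of the sampled x are used (approximate — the
        reconstruction error then scales with the sampling interval).
    """
    if comp.n_species != 2:
        raise DimensionError("total reconstruction requires exactly 2 species")
    r1, r2 = params.r
    B11, B12 = params.B[0]
    B21, B22 = params.B[1]
    x = comp.proportions[:, 0]
    t = comp.times
    if x_derivative is None:
        if comp.total_abundance is not None:
            xp = np.array(
                [
                    compositional_rhs(comp.proportions[k], comp.total_abundance[k], params)[0][0]
                    for k in range(t.size)
                ]
            )
        else:
            xp = np.gradient(x, t)  # centered differences in the interior
    else:
        xp = np.asarray(x_derivative, dtype=float)
        if xp.shape != x.shape:
            raise DimensionError("x_derivative must match the trajectory")
    numer = (r1 - r2) * (x - 1.0) * x + xp
    denom = (x - 1.0) * x * (B22 + B12 * (x - 1.0) - (B11 - B21 + B22) * x)
    singular = np.abs(denom) < tol
    if np.any(singular):
        raise SingularReconstructionError(t[singular])
    return numer / denom
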