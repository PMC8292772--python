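"""Structural identifiability of the gLV model under compositional observation.

For two species the observed composition x = X/(X+Y) satisfies a single
differential-algebraic equation (the input-output relation) in x, x', x''
alone, obtained by eliminating the unobserved total N:

1. rewrite the absolute system in (x, N) coordinates,
2. solve the x' equation for N,
3. substitute N and dN/dt into the N' equation and clear denominators.

The coefficients of the resulting polynomial, after monic normalization by
the leading-order coefficient, are exactly the identifiable quantities.
Solving the coefficient system against an alternative parameter copy
(a1, ..., a6) shows that the growth rates r1, r2 are uniquely identifiable
while the four interaction rates are identifiable only up to one common
multiplicative constant (gauge: B22).

For n >= 3 the symbolic elimination suffers expression swell; the same
up-to-scale structure is checked numerically for arbitrary n by
:func:`numeric_scale_invariance_check` (invariance of the composition under
B -> c B, X0 -> X0 / c) together with its negative control
:func:`numeric_distinguishability_check`.  For communities larger than the
sizes actually tested the up-to-scale statement is a conjecture, not a
verified result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .errors import DegenerateParametrizationError, DerivationError, DimensionError
from .model import GLVParameters, solve_deterministic, to_composition

__all__ = [
    "IORelation",
    "IdentifiabilityReport",
    "PARAM_SYMBOLS",
    "ALT_SYMBOLS",
    "derive_io_relation",
    "make_monic",
    "solve_alternative_parameters",
    "numeric_scale_invariance_check",
    "numeric_distinguishability_check",
]

# Observable and parameter symbols.  x, xp, xpp are the composition of the
# first species and its first two time derivatives.
X_SYM, XP_SYM, XPP_SYM = sp.symbols("x xp xpp")
_N = sp.Symbol("N")
PARAM_SYMBOLS = sp.symbols("r1 r2 b11 b12 b21 b22")
ALT_SYMBOLS = sp.symbols("a1 a2 a3 a4 a5 a6")

#: Parameter names in the order of PARAM_SYMBOLS.
PARAM_NAMES = ("r1", "r2", "b11", "b12", "b21", "b22")

#: Monomial whose coefficient is the leading-order one (powers of x, x', x'').
LEADING_MONOMIAL = (3, 0, 1)


@dataclass(frozen=True)
class IORelation:
    """Input-output polynomial relation 0 = sum coeff * x^i x'^j x''^k.

    ``coefficients`` maps monomials ``(i, j, k)`` — the powers of x, x' and
    x'' — to sympy expressions in the six two-species parameters.  Derivative
    order never exceeds two.  When ``monic`` is set, the coefficient of the
    leading monomial is identically 1 and ``leading_coefficient`` records the
    expression everything was divided by.
    """

    coefficients: dict
    monic: bool
    leading_coefficient: sp.Expr

    def __post_init__(self):
        for (i, j, k) in self.coefficients:
            if k > 1 or j > 2:
                raise DerivationError(
                    f"monomial {(i, j, k)} exceeds second derivative order"
                )
        if self.monic:
            lead = self.coefficients.get(LEADING_MONOMIAL)
            if lead is None or sp.simplify(lead - 1) != 0:
                raise DerivationError("monic relation must have unit leading coefficient")

    def as_expression(self) -> sp.Expr:
        """The full polynomial as a single sympy expression."""
        return sp.Add(
            *(
                c * X_SYM**i * XP_SYM**j * XPP_SYM**k
                for (i, j, k), c in self.coefficients.items()
            )
        )

    def substitute(self, mapping: dict) -> dict:
        """Coefficients with a parameter substitution applied (and cancelled)."""
        return {
            m: sp.cancel(c.subs(mapping)) for m, c in self.coefficients.items()
        }


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Verdict of the alternative-parameter analysis.

    ``identifiable`` and ``scale_class`` partition the parameter set:
    parameters in ``identifiable`` are uniquely determined by the monic
    coefficients; parameters in ``scale_class`` are determined only up to one
    common factor, with ``gauge`` naming the reference parameter.
    ``solution_map`` gives each alternative parameter in terms of the
    originals (free symbols of the alternative copy mark the gauge freedom)
    and ``family_dimension`` is the number of free scales.
    """

    identifiable: tuple
    scale_class: tuple
    gauge: str
    solution_map: dict
    family_dimension: int

    def __post_init__(self):
        overlap = set(self.identifiable) & set(self.scale_class)
        if overlap:
            raise ValueError(f"parameters in both classes: {overlap}")
        if set(self.identifiable) | set(self.scale_class) != set(PARAM_NAMES):
            raise ValueError("classes must cover all model parameters")
        if (self.family_dimension >= 1) != bool(self.scale_class):
            raise ValueError("family dimension inconsistent with scale class")

    def to_dict(self) -> dict:
        return {
            "identifiable": list(self.identifiable),
            "scale_class": list(self.scale_class),
            "gauge": self.gauge,
            "solution_map": {str(k): str(v) for k, v in self.solution_map.items()},
            "family_dimension": self.family_dimension,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def describe(self) -> str:
        lines = [
            "Structural identifiability of the 2-species gLV model from",
            "relative-abundance data:",
            f"  identifiable exactly : {', '.join(self.identifiable)}",
            f"  identifiable up to a common scale : {', '.join(self.scale_class)}",
            f"  gauge (reference) parameter : {self.gauge}",
            f"  dimension of the unidentifiable family : {self.family_dimension}",
        ]
        return "\n".join(lines)


def _io_polynomial(params) -> sp.Poly:
    """Eliminate N from the two-species compositional system symbolically."""
    r1, r2, b11, b12, b21, b22 = params
    x, xp, xpp, N = X_SYM, XP_SYM, XPP_SYM, _N
    X = N * x
    Y = N * (1 - x)
    Xdot = sp.expand(X * (r1 + b11 * X + b12 * Y))
    Ydot = sp.expand(Y * (r2 + b21 * X + b22 * Y))
    Ndot = sp.expand(Xdot + Ydot)
    xdot = sp.cancel(Xdot / N - x * Ndot / N)  # quotient rule
    sols = sp.solve(sp.Eq(xp, xdot), N)
    if len(sols) != 1:
        raise DerivationError(f"expected a unique solution for N, got {len(sols)}")
    N_of_x = sols[0]
    # chain rule: dN/dt in terms of x, x', x''
    dN_dt = sp.diff(N_of_x, x) * xp + sp.diff(N_of_x, xp) * xpp
    residual = sp.together(dN_dt - Ndot.subs(N, N_of_x))
    numerator, _ = sp.fraction(residual)
    return sp.Poly(sp.expand(numerator), xpp, xp, x)


@lru_cache(maxsize=None)
def derive_io_relation() -> IORelation:
    """Derive the two-species input-output relation from scratch.

    Returns the un-normalized polynomial relation; its coefficients are
    polynomials in (r1, r2, b11, b12, b21, b22).  The result is cached —
    the elimination takes about a second of sympy time.
    """
    poly = _io_polynomial(PARAM_SYMBOLS)
    coeffs = {}
    for monom, coeff in zip(poly.monoms(), poly.coeffs()):
        kpp, kp, kx = monom  # Poly generator order is (xpp, xp, x)
        coeffs[(kx, kp, kpp)] = sp.expand(coeff)
    lead = coeffs.get(LEADING_MONOMIAL)
    if lead is None:
        raise DerivationError("leading monomial x''*x^3 absent from the relation")
    return IORelation(coefficients=coeffs, monic=False, leading_coefficient=lead)


def make_monic(rel: IORelation, at_point: dict | None = None) -> IORelation:
    """Divide every coefficient by the leading-order one.

    Parameters
    ----------
    at_point : optional mapping of parameter symbols/names to numbers
        A parameter point at which the leading coefficient
        (b21 - b22) - (b11 - b12) must be nonzero; where it vanishes the DAE
        drops order and the normalization is undefined.
    """
    lead = rel.coefficients[LEADING_MONOMIAL]
    if at_point is not None:
        subs = {sp.Symbol(str(k)): v for k, v in at_point.items()}
        val = complex(lead.subs(subs))
        if abs(val) < 1e-12:
            raise DegenerateParametrizationError(
                f"leading coefficient {lead} vanishes at {at_point}"
            )
    coeffs = {m: sp.cancel(c / lead) for m, c in rel.coefficients.items()}
    return IORelation(coefficients=coeffs, monic=True, leading_coefficient=lead)


def solve_alternative_parameters(rel: IORelation) -> IdentifiabilityReport:
    """Solve the monic coefficient system against an alternative parameter copy.

    Equates each monic coefficient written in the original parameters to the
    same expression in (a1, ..., a6) and solves for the alternative copy.  A
    unique solution for a_i in terms of the originals alone means the matching
    original parameter is identifiable; a solution involving a free
    alternative symbol means the parameter is determined only up to that free
    scale.
    """
    if not rel.monic:
        raise ValueError("solve_alternative_parameters requires a monic relation")
    alt_poly = _io_polynomial(ALT_SYMBOLS)
    alt_lead = alt_poly.coeff_monomial(
        XPP_SYM ** LEADING_MONOMIAL[2] * XP_SYM ** LEADING_MONOMIAL[1] * X_SYM ** LEADING_MONOMIAL[0]
    )
    alt_coeffs = {}
    for monom, coeff in zip(alt_poly.monoms(), alt_poly.coeffs()):
        kpp, kp, kx = monom
        alt_coeffs[(kx, kp, kpp)] = sp.cancel(coeff / alt_lead)
    if set(alt_coeffs) != set(rel.coefficients):
        raise DerivationError("alternative relation has different support")

    equations = [
        sp.Eq(alt_coeffs[m], rel.coefficients[m])
        for m in sorted(rel.coefficients)
        if m != LEADING_MONOMIAL
    ]
    solutions = sp.solve(equations, ALT_SYMBOLS, dict=True)
    if not solutions:
        raise DerivationError("coefficient system has no solution")
    if len(solutions) > 1:
        # report all branches rather than guessing; not expected for gLV
        raise DerivationError(f"multiple solution branches: {solutions}")
    sol = solutions[0]

    alt_of = dict(zip(PARAM_NAMES, ALT_SYMBOLS))
    orig_of = dict(zip(ALT_SYMBOLS, PARAM_SYMBOLS))
    free_alts = [a for a in ALT_SYMBOLS if a not in sol]
    identifiable, scale_class = [], []
    gauge = None
    solution_map = {}
    for name in PARAM_NAMES:
        a = alt_of[name]
        if a in sol:
            expr = sp.simplify(sol[a])
            solution_map[a] = expr
            if expr == orig_of[a] and not (expr.free_symbols & set(ALT_SYMBOLS)):
                identifiable.append(name)
            else:
                scale_class.append(name)
        else:
            # the free alternative symbol marks the gauge parameter
            solution_map[a] = a
            scale_class.append(name)
            gauge = name
    return IdentifiabilityReport(
        identifiable=tuple(identifiable),
        scale_class=tuple(scale_class),
        gauge=gauge,
        solution_map=solution_map,
        family_dimension=len(free_alts),
    )


def _composition_on_grid(params, x0, times):
    traj = solve_deterministic(params, x0, times)
    return to_composition(traj).proportions


def numeric_scale_invariance_check(
    params: GLVParameters,
    c: float,
    initial_abundances: np.ndarray,
    times: np.ndarray,
) -> float:
    """Maximum composition deviation between (r, B, X0) and (r, cB, X0/c).

    For any community size n and any c > 0 the two systems have identical
    composition trajectories; the returned deviation should be at solver
    noise level (<= 10x the integration tolerance).  This is the numeric
    counterpart of the symbolic up-to-scale result for n = 2.
    """
    if c <= 0:
        raise DimensionError("scale c must be positive")
    x0 = np.asarray(initial_abundances, dtype=float)
    p_base = _composition_on_grid(params, x0, times)
    p_scaled = _composition_on_grid(params.scaled(c), x0 / c, times)
    return float(np.max(np.abs(p_base - p_scaled)))


def numeric_distinguishability_check(
    params: GLVParameters,
    perturbed: GLVParameters,
    initial_abundances: np.ndarray,
    times: np.ndarray,
    perturbed_initial_abundances: np.ndarray | None = None,
) -> float:
    """Composition deviation caused by a non-scale parameter perturbation.

    Negative control for :func:`numeric_scale_invariance_check`: perturbing
    growth rates or individual interaction ratios (rather than the common B
    scale together with 1/scale on the initial state) must visibly change the
    composition trajectory.  Returns the max absolute deviation; callers
    assert it exceeds a floor (1e-3 is ample for a 10% perturbation on the
    benchmark systems).  A perturbation along the exact scale direction
    (``perturbed = params.scaled(c)``, ``perturbed_initial_abundances =
    initial_abundances / c``) reduces to the invariance case and yields a
    deviation at solver noise level.
    """
    x0 = np.asarray(initial_abundances, dtype=float)
    x0p = (
        x0
        if perturbed_initial_abundances is None
        else np.asarray(perturbed_initial_abundances, dtype=float)
    )
    p_base = _composition_on_grid(params, x0, times)
    p_pert = _composition_on_grid(perturbed, x0p, times)
    return float(np.max(np.abs(p_base - p_pert)))
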