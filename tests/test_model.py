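"""Core gLV model: vector field, integration, compositional reformulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glvident import (
    AbundanceTrajectory,
    CompositionTrajectory,
    DegenerateSampleError,
    DimensionError,
    GLVParameters,
    SingularReconstructionError,
    UndefinedCarryingCapacityError,
    carrying_capacity,
    compositional_rhs,
    glv_rhs,
    reconstruct_total,
    solve_deterministic,
    to_composition,
)


def scalar_rhs(state, r, B):
    """Independent term-by-term oracle for the gLV vector field."""
    n = len(state)
    out = []
    for i in range(n):
        interaction = 0.0
        for j in range(n):
            interaction += B[i][j] * state[j]
        out.append(state[i] * (r[i] + interaction))
    return out


class TestVectorField:
    def test_matches_scalar_arithmetic_on_benchmark(self, value1_params):
        state = np.array([10.0, 14.0, 4.0])
        expected = scalar_rhs(
            state.tolist(), value1_params.r.tolist(), value1_params.B.tolist()
        )
        np.testing.assert_allclose(glv_rhs(state, value1_params), expected, rtol=1e-14)

    @pytest.mark.parametrize(
        "state,expected",
        [([1.0], [0.0]), ([0.0], [0.0])],
        ids=["carrying-capacity-equilibrium", "extinction-absorbing"],
    )
    def test_single_species_fixed_points(self, state, expected):
        params = GLVParameters([1.0], [[-1.0]])
        np.testing.assert_array_equal(glv_rhs(np.array(state), params), expected)

    def test_dimension_mismatch_rejected(self, value1_params):
        with pytest.raises(DimensionError):
            glv_rhs(np.array([1.0, 2.0]), value1_params)


class TestCarryingCapacity:
    def test_single_species(self):
        np.testing.assert_array_equal(
            carrying_capacity(GLVParameters([1.0], [[-1.0]])), [1.0]
        )

    def test_benchmark_capacities_scale_inversely_with_B(
        self, value1_params, value2_params
    ):
        # -6 / -0.05 = 120 by hand; the 100x-B system has 100x smaller capacity
        assert carrying_capacity(value1_params)[0] == pytest.approx(120.0)
        assert carrying_capacity(value2_params)[0] == pytest.approx(1.2)

    def test_zero_diagonal_names_species(self):
        params = GLVParameters([1.0, 1.0], [[-1.0, 0.5], [0.3, 0.0]])
        with pytest.raises(UndefinedCarryingCapacityError) as err:
            carrying_capacity(params)
        assert err.value.species == (1,)


class TestDeterministicSolve:
    def test_logistic_closed_form(self):
        params = GLVParameters([1.0], [[-1.0]])
        times = np.linspace(0.0, 8.0, 40)
        traj = solve_deterministic(params, np.array([0.5]), times)
        K, N0, r = 1.0, 0.5, 1.0
        closed = K / (1 + (K / N0 - 1) * np.exp(-r * times))
        np.testing.assert_allclose(traj.abundances[:, 0], closed, atol=1e-6)

    def test_single_time_returns_initial_state(self, value1_params, value1_x0):
        traj = solve_deterministic(value1_params, value1_x0, np.array([0.0]))
        np.testing.assert_array_equal(traj.abundances, value1_x0[None, :])

    def test_benchmark_regression_against_tight_tolerance_integrator(
        self, value1_params, value1_x0, short_times
    ):
        from scipy.integrate import solve_ivp

        traj = solve_deterministic(value1_params, value1_x0, short_times)
        oracle = solve_ivp(
            lambda t, y: np.asarray(scalar_rhs(y, value1_params.r, value1_params.B)),
            (0.0, short_times[-1]),
            value1_x0,
            t_eval=short_times,
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
        )
        np.testing.assert_allclose(traj.abundances, oracle.y.T, rtol=1e-5, atol=1e-7)


class TestComposition:
    def test_two_equal_species(self):
        traj = AbundanceTrajectory(np.array([0.0]), np.array([[2.0, 2.0]]))
        comp = to_composition(traj)
        np.testing.assert_array_equal(comp.proportions, [[0.5, 0.5]])

    def test_benchmark_initial_composition(self, value1_x0):
        # N(0) = 28 for value set 1
        traj = AbundanceTrajectory(np.array([0.0]), value1_x0[None, :])
        comp = to_composition(traj)
        np.testing.assert_allclose(comp.proportions[0], np.array([10, 14, 4]) / 28)
        assert comp.total_abundance[0] == pytest.approx(28.0)

    def test_zero_total_row_rejected(self):
        traj = AbundanceTrajectory(np.array([0.0, 1.0]), [[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateSampleError):
            to_composition(traj)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(1, 5)),
            elements=st.floats(1e-6, 1e6),
        )
    )
    def test_rows_always_sum_to_one(self, abundances):
        traj = AbundanceTrajectory(np.arange(abundances.shape[0]), abundances)
        comp = to_composition(traj)
        np.testing.assert_allclose(comp.proportions.sum(axis=1), 1.0, atol=1e-9)


class TestCompositionalRHS:
    def test_two_species_antisymmetry(self, value1_params):
        # y' = -x': the simplex flow components cancel exactly
        params = GLVParameters(value1_params.r[:2], value1_params.B[:2, :2])
        dx, _ = compositional_rhs(np.array([0.3, 0.7]), 5.0, params)
        assert dx[1] == pytest.approx(-dx[0], abs=1e-12)

    def test_neutral_community_is_stationary(self):
        params = GLVParameters([2.0, 2.0, 2.0], np.zeros((3, 3)))
        dx, dN = compositional_rhs(np.array([0.2, 0.3, 0.5]), 4.0, params)
        np.testing.assert_allclose(dx, 0.0, atol=1e-12)
        assert dN == pytest.approx(8.0)

    def test_matches_finite_difference_projection(self):
        rng = np.random.default_rng(11)
        params = GLVParameters(
            rng.uniform(0.5, 2, 3), rng.uniform(-0.5, 0.5, (3, 3))
        )
        state = rng.uniform(0.5, 2, 3)
        N = state.sum()
        x = state / N
        h = 1e-6
        plus = state + h * glv_rhs(state, params)
        minus = state - h * glv_rhs(state, params)
        fd_dx = (plus / plus.sum() - minus / minus.sum()) / (2 * h)
        fd_dN = (plus.sum() - minus.sum()) / (2 * h)
        dx, dN = compositional_rhs(x, N, params)
        np.testing.assert_allclose(dx, fd_dx, atol=1e-4)
        assert dN == pytest.approx(fd_dN, abs=1e-4)

    def test_simplex_tangency(self, value1_params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.dirichlet(np.ones(3))
            dx, _ = compositional_rhs(x, rng.uniform(0.1, 50), value1_params)
            assert abs(dx.sum()) < 1e-10

    def test_off_simplex_rejected(self, value1_params):
        with pytest.raises(DimensionError):
            compositional_rhs(np.array([0.5, 0.2, 0.2]), 1.0, value1_params)


class TestConsistency:
    def test_compositional_and_absolute_routes_agree(self, value1_params, value1_x0):
        from scipy.integrate import solve_ivp

        times = np.linspace(0.0, 5.0, 51)
        absolute = solve_deterministic(value1_params, value1_x0, times)
        projected = to_composition(absolute)

        def rhs(t, state):
            dx, dN = compositional_rhs(state[:-1], state[-1], value1_params)
            return np.append(dx, dN)

        y0 = np.append(value1_x0 / value1_x0.sum(), value1_x0.sum())
        sol = solve_ivp(rhs, (0, 5), y0, t_eval=times, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(projected.proportions, sol.y[:-1].T, atol=1e-6)
        np.testing.assert_allclose(projected.total_abundance, sol.y[-1], rtol=1e-6)

    def test_scale_gauge_preserves_composition(self, value1_params, value1_x0):
        times = np.linspace(0.0, 5.0, 26)
        base = to_composition(solve_deterministic(value1_params, value1_x0, times))
        for c in (0.01, 3.7, 100.0):
            scaled = to_composition(
                solve_deterministic(value1_params.scaled(c), value1_x0 / c, times)
            )
            np.testing.assert_allclose(
                base.proportions, scaled.proportions, atol=1e-7
            )


class TestReconstructTotal:
    @pytest.fixture()
    def two_species(self):
        params = GLVParameters([1.5, 0.8], [[-0.4, 0.1], [-0.2, -0.5]])
        x0 = np.array([1.2, 0.6])
        times = np.linspace(0.0, 4.0, 41)
        traj = solve_deterministic(params, x0, times)
        return params, to_composition(traj)

    def test_recovers_integrated_total_with_analytic_derivative(self, two_species):
        params, comp = two_species
        xp = np.array(
            [
                compositional_rhs(comp.proportions[k], comp.total_abundance[k], params)[0][0]
                for k in range(comp.times.size)
            ]
        )
        N = reconstruct_total(comp, params, x_derivative=xp)
        np.testing.assert_allclose(N, comp.total_abundance, rtol=1e-6)

    def test_homogeneity_in_interaction_scale(self, two_species):
        # same (x, x') data, B -> 10 B  =>  reconstructed N -> N / 10
        params, comp = two_species
        xp = np.gradient(comp.proportions[:, 0], comp.times)
        N = reconstruct_total(comp, params, x_derivative=xp)
        N_scaled = reconstruct_total(comp, params.scaled(10.0), x_derivative=xp)
        np.testing.assert_allclose(N_scaled, N / 10.0, rtol=1e-12)

    def test_equilibrium_composition_gives_equilibrium_total(self):
        params = GLVParameters([1.0, 0.8], [[-1.0, -0.2], [-0.3, -0.9]])
        star = np.linalg.solve(params.B, -params.r)  # interior equilibrium
        x_star = star / star.sum()
        comp = CompositionTrajectory(
            np.array([0.0, 1.0]), np.vstack([x_star, x_star])
        )
        N = reconstruct_total(comp, params, x_derivative=np.zeros(2))
        np.testing.assert_allclose(N, star.sum(), rtol=1e-10)

    def test_singular_denominator_reported_with_times(self):
        # identical rows of B make the denominator vanish identically
        params = GLVParameters([1.0, 2.0], [[-1.0, -1.0], [-1.0, -1.0]])
        comp = CompositionTrajectory(np.array([0.0, 1.0]), [[0.4, 0.6], [0.4, 0.6]])
        with pytest.raises(SingularReconstructionError) as err:
            reconstruct_total(comp, params, x_derivative=np.zeros(2))
        assert err.value.times == (0.0, 1.0)

    def test_requires_two_species(self, value1_params):
        comp = CompositionTrajectory(np.array([0.0]), [[0.2, 0.3, 0.5]])
        with pytest.raises(DimensionError):
            reconstruct_total(comp, value1_params)
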