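"""Prolongation, determining equations and symmetry verification."""

import numpy as np
import pytest
import sympy as sp

from dnalie.lie_engine import (
    U,
    VectorField,
    determining_system,
    jet,
    paper_generators,
    prolong,
    prolongation_coefficient_oracle,
    same_span,
    solve_determining,
    verify_symmetry,
)
from dnalie.model_core import PDEModel, alpha, gamma, t, z

ALL_INDICES = [(i, j) for n in range(1, 5) for i in range(n + 1) for j in [n - i]]


class TestProlongation:
    def test_pure_u_translation_has_zero_coefficients(self):
        pf = prolong(VectorField(0, 0, 1), 4)
        for J, coeff in pf.eta_J.items():
            if J != (0, 0):
                assert coeff == 0

    def test_boost_generator_first_order(self):
        # Y4 = t d/du: one recursion step gives eta_t = 1 and eta_z = 0
        pf = prolong(VectorField(0, 0, t), 2)
        assert pf.eta_J[(0, 1)] == 1
        assert pf.eta_J[(1, 0)] == 0
        assert pf.eta_J[(2, 0)] == 0

    def test_order_out_of_range(self):
        with pytest.raises(ValueError):
            prolong(VectorField(0, 0, 1), 5)

    @pytest.mark.parametrize("index", [(1, 1), (2, 0), (0, 2), (2, 2), (1, 3)])
    def test_recursion_matches_characteristic_oracle(self, fixture_set, index):
        # independent route: eta^J = D^J Q + xi_z u_{J,z} + xi_t u_{J,t}
        for field in fixture_set.vector_fields[:3]:
            pf = prolong(field, 4)
            oracle = prolongation_coefficient_oracle(field, index)
            assert sp.expand(pf.eta_J[index] - oracle) == 0

    def test_prolongation_linearity(self, fixture_set):
        a, b = sp.Rational(3, 2), sp.Rational(-2, 5)
        X, Y = fixture_set.vector_fields[:2]
        lhs = prolong(a * X + b * Y, 3)
        px, py = prolong(X, 3), prolong(Y, 3)
        for J in lhs.eta_J:
            assert sp.expand(lhs.eta_J[J] - a * px.eta_J[J] - b * py.eta_J[J]) == 0


class TestDeterminingSystem:
    @pytest.mark.parametrize("degree,expected_dim", [(1, 5), (2, 5), (3, 5)])
    def test_solution_space_dimension(self, degree, expected_dim):
        system = determining_system(ansatz_degree=degree)
        assert system.solution_dimension == expected_dim

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            determining_system(ansatz_degree=0)

    def test_equations_are_homogeneous(self):
        system = determining_system(ansatz_degree=1)
        system.coefficient_matrix()  # raises if inhomogeneous

    def test_degree2_basis_spans_published_algebra(self, solved_basis):
        assert len(solved_basis) == 5
        assert same_span(solved_basis, paper_generators())

    def test_degree1_solutions_inside_published_span(self):
        basis = solve_determining(determining_system(ansatz_degree=1))
        combined = basis + paper_generators()
        # adding the printed generators must not enlarge the span
        assert same_span(combined, paper_generators())

    def test_general_infinitesimal_shape(self, solved_basis):
        # xi_z constant, xi_t affine in t, eta affine in (u, z, t)
        for f in solved_basis:
            assert sp.diff(f.xi_z, z) == 0 and sp.diff(f.xi_z, t) == 0 and sp.diff(f.xi_z, U) == 0
            assert sp.diff(f.xi_t, t, 2) == 0 and sp.diff(f.xi_t, z) == 0
            assert sp.diff(f.eta, U, 2) == 0 and sp.diff(f.eta, z, 2) == 0


class TestVerifySymmetry:
    @pytest.mark.parametrize("i", range(5))
    def test_published_generators_are_symmetries(self, i):
        assert sp.simplify(verify_symmetry(paper_generators()[i])) == 0

    def test_space_scaling_is_not_a_symmetry(self):
        assert sp.simplify(verify_symmetry(VectorField(z, 0, 0))) != 0

    def test_random_combination_is_symmetry(self):
        rng = np.random.default_rng(7)
        gens = paper_generators()
        combo = VectorField()
        for g in gens:
            combo = combo + sp.Rational(int(rng.integers(-5, 6)), int(rng.integers(1, 4))) * g
        assert sp.simplify(verify_symmetry(combo)) == 0

    def test_negative_control_fields_fail(self, fixture_set):
        # generic degree-2 fields are not symmetries
        failures = 0
        for f in fixture_set.vector_fields:
            if sp.simplify(verify_symmetry(f)) != 0:
                failures += 1
        assert failures == len(fixture_set.vector_fields)
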