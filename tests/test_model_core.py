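"""The PDE residual operator: symbolic and gridded numeric evaluation."""

import numpy as np
import pytest
import sympy as sp

from dnalie.model_core import (
    GridSpec,
    NonDifferentiableError,
    PDEModel,
    alpha,
    beta,
    gamma,
    numeric_residual,
    pde_residual,
    t,
    z,
)

c1, c2 = sp.symbols("c1 c2", real=True)


class TestPDEModel:
    def test_zero_parameters_rejected(self):
        with pytest.raises(ValueError):
            PDEModel(gamma=0)
        with pytest.raises(ValueError):
            PDEModel(alpha=0)

    def test_residual_operator_shape(self):
        # Delta stored exactly as the left-hand side, never rescaled by alpha^2
        expr = PDEModel().residual_operator()
        u = sp.Function("u")(z, t)
        assert sp.expand(expr - (
            u.diff(t, 2)
            - alpha**2 * u.diff(z, 2)
            + beta / alpha**2 * u.diff(z, 2, t, 2)
            - gamma * sp.diff(u.diff(z) ** 2, z)
        )) == 0


class TestSymbolicResidual:
    @pytest.mark.parametrize(
        "candidate",
        [c1 * z + c2, sp.S.Zero, c1 * t + c2],
        ids=["space-linear", "zero", "time-linear"],
    )
    def test_exact_solutions_give_zero(self, candidate):
        assert pde_residual(candidate) == 0

    def test_sine_is_not_a_solution(self):
        # direct differentiation: u = sin z gives alpha^2 sin z + 2 gamma sin z cos z
        model = PDEModel(alpha=1, gamma=1, beta=1)
        res = pde_residual(sp.sin(z), model)
        assert sp.simplify(res - (sp.sin(z) + 2 * sp.sin(z) * sp.cos(z))) == 0

    def test_kinked_candidate_raises_naming_derivative(self):
        with pytest.raises(NonDifferentiableError, match="u_"):
            pde_residual(sp.Abs(z) * t)

    def test_nonlinear_flux_cross_terms(self):
        # residual(u1+u2) - residual(u1) - residual(u2) = -2 gamma (u1_z u2_z)_z
        rng = np.random.default_rng(42)
        for _ in range(3):
            coeffs = rng.integers(-3, 4, size=8)
            u1 = coeffs[0] * z**2 + coeffs[1] * z * t + coeffs[2] * t**2 + coeffs[3] * z
            u2 = coeffs[4] * z**3 + coeffs[5] * t**2 * z + coeffs[6] * t + coeffs[7] * z * t
            cross = pde_residual(u1 + u2, do_simplify=False) - pde_residual(
                u1, do_simplify=False
            ) - pde_residual(u2, do_simplify=False)
            expected = -2 * gamma * sp.diff(sp.diff(u1, z) * sp.diff(u2, z), z)
            assert sp.expand(cross - expected) == 0


class TestNumericResidual:
    def test_boost_solution_numeric_zero(self):
        # the 3/2-power invariant solution on the unit square
        from dnalie.exact_solutions import printed_invariant_solutions

        expr = printed_invariant_solutions()["Lambda7+"].subs(
            {c1: 1, c2: 1, alpha: 1, gamma: 1}
        )
        model = PDEModel(alpha=1, gamma=1, beta=1)
        rep = numeric_residual(expr, model, GridSpec((0, 1), (0, 1)))
        assert rep.symbolic_zero
        assert rep.max_abs_residual < 1e-8

    def test_time_linear_machine_zero(self):
        rep = numeric_residual(c1.subs(c1, 3) * t + 2, PDEModel(alpha=2, gamma=1, beta=1))
        assert rep.max_abs_residual == 0.0

    def test_non_solution_strictly_positive(self):
        rep = numeric_residual(z * t**2, PDEModel(alpha=1, gamma=2, beta=1))
        assert rep.max_abs_residual > 0.1
        assert not rep.symbolic_zero

    def test_blackbox_callable_matches_symbolic(self):
        model = PDEModel(alpha=1, gamma=2, beta=1)
        grid = GridSpec((0, 1), (0, 1), 30, 30)
        sym = numeric_residual(z * t**2, model, grid)
        num = numeric_residual(lambda Z, T: Z * T**2, model, grid)
        assert abs(num.max_abs_residual - sym.max_abs_residual) < 1e-5

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            numeric_residual(
                lambda Z, T: np.full_like(Z, np.nan), PDEModel(alpha=1, gamma=1, beta=1)
            )

    def test_report_serializes(self):
        rep = numeric_residual(z * t, PDEModel(), GridSpec((0, 1), (0, 1), 5, 5))
        data = rep.to_json()
        assert '"max_abs_residual"' in data
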