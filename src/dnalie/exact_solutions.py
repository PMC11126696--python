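"""Closed-form invariant solutions from the quadrature-solvable reductions.

The first- and second-order reduced ODEs all have the shape

    A h' h'' + B h'' + C = 0,   A, B, C free of h,

possibly with C = 0 (then the equation factors as h'' (A h' + B) = 0).
Integrating once gives (A/2) h'^2 + B h' + C sigma = const; each root of
the quadratic in h' is integrated again, which is where the 3/2-power
branches of the boost-invariant solutions come from.  Assembled solutions
are verified against the PDE before being returned; a failing verification
is flagged, never hidden.

Fourth-order or sigma-explicit reductions are signalled as numeric-only
and handled by :mod:`dnalie.numeric_lab`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import sympy as sp

from .model_core import PDEModel, alpha, gamma, t, z
from .reduction_engine import SimilarityReduction, h, sigma

__all__ = [
    "c1",
    "c2",
    "NumericOnlyError",
    "ClosedFormSolution",
    "integrate_reduced",
    "assemble",
    "printed_invariant_solutions",
    "invariant_solution_catalog",
]

#: integration constants, named as in the published solutions
c1, c2 = sp.symbols("c1 c2", real=True)


class NumericOnlyError(ValueError):
    """The reduced ODE is outside the implemented quadrature patterns."""


@dataclass(frozen=True)
class ClosedFormSolution:
    """A closed-form solution with free constants c1, c2.

    ``expression`` is in (z, t) after assembly (or in sigma before);
    ``constraints`` collects parameter/domain conditions, e.g. a nonnegative
    radicand for the 3/2-power branches; ``branch`` names the root taken.
    """

    expression: sp.Expr
    source: str = ""
    constraints: tuple = ()
    branch: str = ""
    residual: sp.Expr = sp.S.Zero
    verified: bool = True


def _ode_coefficients(ode: sp.Expr):
    """Write the ODE as A h'h'' + B h'' + C; raise NumericOnly otherwise."""
    hp = h(sigma).diff(sigma)
    hpp = h(sigma).diff(sigma, 2)
    expr = sp.expand(ode)
    derivs = expr.atoms(sp.Derivative)
    bare_h = expr.xreplace({d: sp.Dummy() for d in derivs}).has(h(sigma))
    if any(d.derivative_count > 2 for d in derivs) or bare_h:
        raise NumericOnlyError("reduced ODE is not first-order reducible; solve numerically")
    poly = sp.Poly(expr, hp, hpp)
    A = B = C = sp.S.Zero
    for mono, coeff in poly.terms():
        if mono == (1, 1):
            A = coeff
        elif mono == (0, 1):
            B = coeff
        elif mono == (0, 0):
            C = coeff
        else:
            raise NumericOnlyError(f"unsupported term h'^{mono[0]} h''^{mono[1]} in reduced ODE")
    if C.has(sigma) or A.has(sigma) or B.has(sigma):
        raise NumericOnlyError("sigma-dependent coefficients; solve numerically")
    return A, B, C


def integrate_reduced(ode: sp.Expr) -> list[ClosedFormSolution]:
    """Integrate a quadrature-solvable reduced ODE; one solution per branch."""
    A, B, C = _ode_coefficients(ode)
    sols: list[ClosedFormSolution] = []
    if C == 0:
        # factored form h'' (A h' + B) = 0
        sols.append(
            ClosedFormSolution(c1 * sigma + c2, branch="h''=0")
        )
        if A != 0:
            sols.append(
                ClosedFormSolution(
                    c1 - B / A * sigma,
                    branch=f"{sp.expand(A*h(sigma).diff(sigma)+B)} = 0",
                )
            )
        return sols
    if A == 0:
        if B == 0:
            raise NumericOnlyError("no derivative term left")
        sols.append(
            ClosedFormSolution(-C / (2 * B) * sigma**2 + c1 * sigma + c2, branch="linear")
        )
        return sols
    # first integral: (A/2) h'^2 + B h' + C sigma = (A/2) c1' + ... ; encode the
    # published constant convention through the radicand B^2 - 2A(C sigma - k)
    k = A * C * c1 * 2 / (2 * C)  # = A*c1: keeps the radicand in the printed shape
    radicand = sp.expand(B**2 - 2 * A * C * sigma + 2 * A * C * c1)
    for sign, name in ((1, "+sqrt"), (-1, "-sqrt")):
        hprime = (-B + sign * sp.sqrt(radicand)) / A
        expr = sp.expand(
            -B / A * sigma - sign * radicand ** sp.Rational(3, 2) / (3 * A**2 * C) + c2
        )
        # sanity: d/dsigma of the integral reproduces the root
        assert sp.simplify(sp.diff(expr, sigma) - hprime) == 0
        sols.append(
            ClosedFormSolution(
                expr,
                branch=name,
                constraints=(sp.Ge(radicand, 0),),
            )
        )
    return sols


def assemble(
    red: SimilarityReduction, h_solution: ClosedFormSolution, model: PDEModel | None = None
) -> ClosedFormSolution:
    """Substitute h back through the solution form and verify against the PDE."""
    from .model_core import pde_residual

    model = model or PDEModel()
    u_expr = red.form.replace(h, sp.Lambda(sigma, h_solution.expression))
    u_expr = sp.simplify(sp.expand(u_expr))
    residual = sp.simplify(pde_residual(u_expr, model))
    verified = residual == 0
    return ClosedFormSolution(
        expression=u_expr,
        source=h_solution.source,
        constraints=h_solution.constraints,
        branch=h_solution.branch,
        residual=residual,
        verified=verified,
    )


def printed_invariant_solutions() -> dict[str, sp.Expr]:
    """The seven published closed-form invariant solutions u(z, t)."""
    rad_p = (4 * c1 + 4 * z) * gamma + alpha**4
    rad_m = (-4 * c1 - 4 * z) * gamma + alpha**4
    return {
        "Lambda9/linear": c1 * z + c2,
        "Lambda9/slope": c1 - alpha**2 / (2 * gamma) * z,
        "Lambda6": c1 * t + c2,
        "Lambda7+": (
            (6 * t**2 + 12 * c2) * gamma**2
            - 6 * alpha**2 * gamma * z
            + rad_p ** sp.Rational(3, 2)
        )
        / (12 * gamma**2),
        "Lambda7-": (
            (-6 * t**2 + 12 * c2) * gamma**2
            - 6 * alpha**2 * gamma * z
            + rad_m ** sp.Rational(3, 2)
        )
        / (12 * gamma**2),
        "Lambda4+": (c1 + z) * t + c2,
        "Lambda4-": (c1 - z) * t + c2,
    }


def invariant_solution_catalog(model: PDEModel | None = None) -> dict[str, ClosedFormSolution]:
    """Re-derive, assemble and verify the invariant solutions per class.

    Returns one entry per published solution; branches whose closed form
    matches the printed one are keyed like :func:`printed_invariant_solutions`.
    """
    from .reduction_engine import reduction_for_class

    model = model or PDEModel()
    printed = printed_invariant_solutions()
    out: dict[str, ClosedFormSolution] = {}

    def best_match(key: str, red: SimilarityReduction, candidates):
        """Keep the branch equal to the printed solution modulo constants."""
        target = printed[key]
        for sol in candidates:
            assembled = assemble(red, sol, model)
            sub = _constant_relabeling(assembled.expression, target)
            if sub is not None:
                out[key] = ClosedFormSolution(
                    assembled.expression.subs(sub),
                    source=key,
                    constraints=tuple(cst.subs(sub) for cst in assembled.constraints),
                    branch=sol.branch,
                    residual=assembled.residual,
                    verified=assembled.verified,
                )
                return
        # fall back to the first branch, flagged by its own verification state
        assembled = assemble(red, candidates[0], model)
        out[key] = assembled

    red = reduction_for_class("Lambda9", model)
    sols = integrate_reduced(red.reduced_ode)
    best_match("Lambda9/linear", red, sols)
    best_match("Lambda9/slope", red, sols)
    red = reduction_for_class("Lambda6", model)
    best_match("Lambda6", red, integrate_reduced(red.reduced_ode))
    for key in ("Lambda7+", "Lambda7-", "Lambda4+", "Lambda4-"):
        red = reduction_for_class(key, model)
        best_match(key, red, integrate_reduced(red.reduced_ode))
    return out


def _constant_relabeling(a: sp.Expr, b: sp.Expr) -> dict | None:
    """A relabeling of the free constants making a equal b, or None.

    Free integration constants are only defined up to invertible relabeling;
    the candidates tried here (identity and c1 -> -c1) cover the sign
    conventions in the published list.
    """
    for sub in ({}, {c1: -c1}):
        if sp.simplify(sp.expand(a.subs(sub) - b)) == 0:
            return sub
    return None


def _same_modulo_constants(a: sp.Expr, b: sp.Expr) -> bool:
    """Equality allowing the free constants to be relabelled."""
    return _constant_relabeling(a, b) is not None
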