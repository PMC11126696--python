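"""Lie point symmetries of the DNA PDE.

A point symmetry is a vector field

    Y = xi_z(z,t,u) d/dz + xi_t(z,t,u) d/dt + eta(z,t,u) d/du

whose fourth prolongation annihilates the PDE residual Delta on the
solution manifold, ``Y^[4](Delta)|_{Delta=0} = 0``.  This module implements
the jet-space machinery (total derivatives, prolongation coefficients via
the standard total-derivative recursion), assembles the linear determining
system by splitting the on-shell symmetry condition on independent
derivative monomials, and solves it within a polynomial coefficient ansatz.

On-shell reduction eliminates the highest mixed derivative u_zztt, which
enters Delta linearly with constant coefficient beta/alpha^2.

The symmetry algebra of the model is five-dimensional, spanned by time,
displacement and space translations, a Galilean-type boost t d/du, and a
scaling-shear generator t d/dt + (-2u - (alpha^2/gamma) z) d/du.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement

import sympy as sp

from .model_core import PDEModel, alpha, beta, gamma, t, z

__all__ = [
    "U",
    "jet",
    "total_derivative",
    "VectorField",
    "ProlongedField",
    "DeterminingSystem",
    "prolong",
    "prolongation_coefficient_oracle",
    "determining_system",
    "solve_determining",
    "verify_symmetry",
    "symmetry_generators",
    "paper_generators",
    "span_matrix",
    "same_span",
]

#: the dependent variable as a plain jet coordinate (u with no derivatives)
U = sp.Symbol("u", real=True)

_MAX_JET_ORDER = 5  # order-4 prolongation plus one total derivative


@lru_cache(maxsize=None)
def jet(i: int, j: int) -> sp.Symbol:
    """Jet coordinate for d^{i+j} u / dz^i dt^j (``jet(0,0)`` is u itself)."""
    if i < 0 or j < 0 or i + j > _MAX_JET_ORDER:
        raise ValueError(f"jet index ({i},{j}) out of range")
    if i == 0 and j == 0:
        return U
    return sp.Symbol(f"u_z{i}t{j}", real=True)


def _jet_indices(max_order: int, min_order: int = 0):
    for n in range(min_order, max_order + 1):
        for i in range(n + 1):
            yield (i, n - i)


def total_derivative(expr: sp.Expr, var: sp.Symbol) -> sp.Expr:
    """Total derivative D_z or D_t on a jet-space expression."""
    if var == z:
        step = (1, 0)
    elif var == t:
        step = (0, 1)
    else:
        raise ValueError("total derivative only along z or t")
    out = sp.diff(expr, var)
    for (i, j) in _jet_indices(_MAX_JET_ORDER - 1):
        s = jet(i, j)
        if expr.has(s):
            out += jet(i + step[0], j + step[1]) * sp.diff(expr, s)
    return sp.expand(out)


@dataclass(frozen=True)
class VectorField:
    """Point-symmetry candidate: coefficients of d/dz, d/dt, d/du.

    Coefficients are sympy expressions in (z, t, u); u is the plain symbol
    :data:`U`.  Vector fields form a linear space: ``+``, ``-`` and scalar
    multiplication are supported.
    """

    xi_z: sp.Expr = sp.S.Zero
    xi_t: sp.Expr = sp.S.Zero
    eta: sp.Expr = sp.S.Zero

    def __post_init__(self):
        for name in ("xi_z", "xi_t", "eta"):
            object.__setattr__(self, name, sp.sympify(getattr(self, name)))

    def __add__(self, other: "VectorField") -> "VectorField":
        return VectorField(self.xi_z + other.xi_z, self.xi_t + other.xi_t, self.eta + other.eta)

    def __sub__(self, other: "VectorField") -> "VectorField":
        return self + (-1) * other

    def __rmul__(self, scalar) -> "VectorField":
        scalar = sp.sympify(scalar)
        return VectorField(scalar * self.xi_z, scalar * self.xi_t, scalar * self.eta)

    __mul__ = __rmul__

    def __call__(self, f: sp.Expr) -> sp.Expr:
        """Apply the first-order operator to a function of (z, t, u)."""
        return (
            self.xi_z * sp.diff(f, z) + self.xi_t * sp.diff(f, t) + self.eta * sp.diff(f, U)
        )

    def is_zero(self) -> bool:
        return all(sp.expand(c) == 0 for c in (self.xi_z, self.xi_t, self.eta))

    def equals(self, other: "VectorField") -> bool:
        return (self - other).simplify().is_zero()

    def simplify(self) -> "VectorField":
        return VectorField(*(sp.cancel(sp.expand(c)) for c in (self.xi_z, self.xi_t, self.eta)))

    def characteristic(self) -> sp.Expr:
        """Q = eta - xi_z u_z - xi_t u_t."""
        return self.eta - self.xi_z * jet(1, 0) - self.xi_t * jet(0, 1)

    def __repr__(self) -> str:
        parts = []
        for c, d in ((self.xi_z, "d/dz"), (self.xi_t, "d/dt"), (self.eta, "d/du")):
            if sp.expand(c) != 0:
                parts.append(f"({c})*{d}")
        return " + ".join(parts) if parts else "0"


@dataclass(frozen=True)
class ProlongedField:
    """A vector field plus its prolongation coefficients eta^J.

    ``eta_J`` maps derivative multi-indices (i, j) -- i z-derivatives and
    j t-derivatives, total order up to the prolongation order -- to jet-space
    expressions; the empty index (0, 0) is the base eta.
    """

    base: VectorField
    order: int
    eta_J: dict

    def apply(self, expr: sp.Expr) -> sp.Expr:
        """Apply Y^[order] to a jet-space expression."""
        out = self.base.xi_z * sp.diff(expr, z) + self.base.xi_t * sp.diff(expr, t)
        for (i, j), coeff in self.eta_J.items():
            s = jet(i, j)
            if expr.has(s):
                out += coeff * sp.diff(expr, s)
        return sp.expand(out)


def prolong(field: VectorField, order: int) -> ProlongedField:
    """Prolong a vector field to derivative coordinates of total order <= order.

    Uses the standard recursion
    ``eta^{J,k} = D_k eta^J - (D_k xi_z) u_{J,z} - (D_k xi_t) u_{J,t}``,
    extending each index first in z then in t (deterministic path; the result
    is path-independent, which the test suite checks against the
    characteristic-formula oracle).
    """
    if not 1 <= order <= 4:
        raise ValueError(f"prolongation order must be in 1..4, got {order}")
    eta_J: dict = {(0, 0): sp.expand(field.eta)}
    for n in range(1, order + 1):
        for i in range(n, -1, -1):
            j = n - i
            if i > 0:
                parent, var, pz, pt = (i - 1, j), z, (i, j), (i - 1, j + 1)
            else:
                parent, var, pz, pt = (i, j - 1), t, (i + 1, j - 1), (i, j)
            eta_J[(i, j)] = sp.expand(
                total_derivative(eta_J[parent], var)
                - total_derivative(field.xi_z, var) * jet(*pz)
                - total_derivative(field.xi_t, var) * jet(*pt)
            )
    return ProlongedField(base=field, order=order, eta_J=eta_J)


def prolongation_coefficient_oracle(field: VectorField, index: tuple[int, int]) -> sp.Expr:
    """Independent route to eta^J: D^J Q + xi_z u_{J,z} + xi_t u_{J,t}."""
    i, j = index
    expr = field.characteristic()
    for _ in range(i):
        expr = total_derivative(expr, z)
    for _ in range(j):
        expr = total_derivative(expr, t)
    return sp.expand(expr + field.xi_z * jet(i + 1, j) + field.xi_t * jet(i, j + 1))


def _delta_jet(model: PDEModel) -> sp.Expr:
    """Delta written in jet coordinates; (u_z^2)_z = 2 u_z u_zz."""
    return (
        jet(0, 2)
        - model.alpha**2 * jet(2, 0)
        + model.beta / model.alpha**2 * jet(2, 2)
        - 2 * model.gamma * jet(1, 0) * jet(2, 0)
    )


def _on_shell_u_zztt(model: PDEModel) -> sp.Expr:
    """Solve Delta = 0 for the highest mixed derivative u_zztt."""
    return (model.alpha**2 / model.beta) * (
        model.alpha**2 * jet(2, 0) + 2 * model.gamma * jet(1, 0) * jet(2, 0) - jet(0, 2)
    )


def _symmetry_condition(field: VectorField, model: PDEModel) -> sp.Expr:
    """Y^[4](Delta) reduced on shell, cleared of alpha/beta denominators."""
    pf = prolong(field, 4)
    s = pf.apply(_delta_jet(model))
    s = s.subs(jet(2, 2), _on_shell_u_zztt(model))
    # alpha^2 and beta are nonzero; clearing them keeps the zero set intact
    return sp.expand(s * model.alpha**2 * model.beta)


def verify_symmetry(field: VectorField, model: PDEModel | None = None) -> sp.Expr:
    """Return the on-shell symmetry residual; identically zero iff symmetry."""
    model = model or PDEModel()
    return sp.cancel(_symmetry_condition(field, model))


@dataclass(frozen=True)
class DeterminingSystem:
    """Linear homogeneous system on the polynomial-ansatz constants."""

    unknowns: tuple
    equations: tuple
    ansatz: tuple  # (xi_z, xi_t, eta) in terms of the unknowns
    ansatz_degree: int

    def coefficient_matrix(self) -> sp.Matrix:
        A, rhs = sp.linear_eq_to_matrix(list(self.equations), list(self.unknowns))
        if any(r != 0 for r in rhs):
            raise RuntimeError("determining system is not homogeneous (bug)")
        return A

    @property
    def solution_dimension(self) -> int:
        A = self.coefficient_matrix()
        return A.cols - A.rank()


def _poly_ansatz(degree: int, prefix: str) -> tuple[sp.Expr, list]:
    # all monomials in (z, t, u) of total degree <= degree
    monos = [sp.S.One]
    for n in range(1, degree + 1):
        monos += [sp.Mul(*c) for c in combinations_with_replacement((z, t, U), n)]
    consts = [sp.Symbol(f"{prefix}{k}") for k in range(len(monos))]
    return sum(c * m for c, m in zip(consts, monos)), consts


def determining_system(model: PDEModel | None = None, ansatz_degree: int = 2) -> DeterminingSystem:
    """Assemble the determining equations within a polynomial ansatz.

    The prolonged field is applied to Delta, u_zztt is eliminated on shell,
    and the result is split on monomials in the remaining independent jet
    coordinates and in (z, t, u).  Each split coefficient is a linear
    homogeneous constraint on the ansatz constants.
    """
    if ansatz_degree < 1:
        raise ValueError("ansatz degree must be >= 1")
    model = model or PDEModel()
    xi_z_a, c1 = _poly_ansatz(ansatz_degree, "a")
    xi_t_a, c2 = _poly_ansatz(ansatz_degree, "b")
    eta_a, c3 = _poly_ansatz(ansatz_degree, "e")
    unknowns = tuple(c1 + c2 + c3)
    field = VectorField(xi_z_a, xi_t_a, eta_a)
    s = _symmetry_condition(field, model)

    gens = [jet(i, j) for (i, j) in _jet_indices(4, min_order=1) if (i, j) != (2, 2)]
    eqs = []
    for coeff in sp.Poly(s, *gens).coeffs():
        for c in sp.Poly(coeff, z, t, U).coeffs():
            c = sp.expand(c)
            if c != 0:
                eqs.append(c)
    return DeterminingSystem(
        unknowns=unknowns,
        equations=tuple(eqs),
        ansatz=(xi_z_a, xi_t_a, eta_a),
        ansatz_degree=ansatz_degree,
    )


def solve_determining(system: DeterminingSystem) -> list[VectorField]:
    """Solve the linear determining system; return a basis of vector fields.

    Rank deficiency is the expected outcome (the solution space is the
    symmetry algebra); an inconsistent system would signal a bug upstream
    and raises.
    """
    A = system.coefficient_matrix()
    null = A.nullspace()
    basis = []
    for vec in null:
        subs = dict(zip(system.unknowns, vec))
        f = VectorField(*(expr.subs(subs) for expr in system.ansatz)).simplify()
        # clear an overall rational denominator for readability
        basis.append(f)
    return basis


def symmetry_generators(model: PDEModel | None = None, ansatz_degree: int = 2) -> list[VectorField]:
    """Convenience: assemble and solve the determining system."""
    return solve_determining(determining_system(model, ansatz_degree))


def paper_generators(model: PDEModel | None = None) -> list[VectorField]:
    """The five generators Y1..Y5 in the conventional order.

    Y1 = d/dt, Y2 = d/du, Y3 = d/dz, Y4 = t d/du,
    Y5 = t d/dt + (-2u - (alpha^2/gamma) z) d/du.
    """
    model = model or PDEModel()
    a, g = model.alpha, model.gamma
    return [
        VectorField(0, 1, 0),
        VectorField(0, 0, 1),
        VectorField(1, 0, 0),
        VectorField(0, 0, t),
        VectorField(0, t, -2 * U - a**2 / g * z),
    ]


def _coeff_vector(field: VectorField, monos: list[sp.Expr]) -> list[sp.Expr]:
    row = []
    for expr in (field.xi_z, field.xi_t, field.eta):
        p = sp.Poly(sp.expand(expr), z, t, U)
        lookup = {sp.Mul(*(g**e for g, e in zip((z, t, U), m))): c for m, c in p.terms()}
        row += [lookup.get(m, sp.S.Zero) for m in monos]
    return row


def span_matrix(fields: list[VectorField], degree: int = 3) -> sp.Matrix:
    """Row-reduced coefficient matrix over an ordered (z, t, u) monomial list.

    Basis vectors are only defined up to linear combination; comparing the
    reduced row-echelon forms of two bases decides span equality.
    """
    monos = [sp.S.One]
    for n in range(1, degree + 1):
        monos += [sp.Mul(*c) for c in combinations_with_replacement((z, t, U), n)]
    M = sp.Matrix([_coeff_vector(f, monos) for f in fields])
    R = M.rref()[0]
    nonzero = [i for i in range(R.rows) if any(x != 0 for x in R.row(i))]
    return R[nonzero, :]


def same_span(fields_a: list[VectorField], fields_b: list[VectorField]) -> bool:
    """Do two lists of vector fields span the same linear space?"""
    ra = span_matrix(fields_a)
    rb = span_matrix(fields_b)
    if ra.shape != rb.shape:
        return False
    return sp.simplify(ra - rb) == sp.zeros(*ra.shape)
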