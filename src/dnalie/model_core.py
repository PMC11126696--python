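"""Canonical form of the microwave-driven DNA displacement PDE.

The model describes the difference in longitudinal displacement u(z, t)
between the two strands of a DNA double helix driven by an external
microwave field:

    u_tt - alpha^2 u_zz + (beta / alpha^2) u_zztt - gamma (u_z^2)_z = 0

where ``alpha`` is the linear wave speed, ``gamma`` the coefficient of the
nonlinear elastic flux and ``beta`` the dispersion coefficient of the
fourth-order mixed term.  All three are treated as dimensionless reals;
``alpha`` and ``gamma`` must be nonzero because they appear in
denominators of the invariant solutions.

This module owns the symbols, the residual operator Delta (stored exactly
as the left-hand side above, never rescaled), and symbolic / gridded
numeric residual evaluation for arbitrary candidate solutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "z",
    "t",
    "u",
    "alpha",
    "gamma",
    "beta",
    "PDEModel",
    "GridSpec",
    "ResidualReport",
    "NonDifferentiableError",
    "pde_residual",
    "numeric_residual",
    "DEFAULT_TOLERANCE",
]

#: independent space / time symbols and the dependent displacement symbol
z, t = sp.symbols("z t", real=True)
u = sp.Function("u")

#: model parameters (dimensionless reals)
alpha, gamma, beta = sp.symbols("alpha gamma beta", real=True, nonzero=True)

#: absolute threshold below which a gridded residual counts as numerically zero
DEFAULT_TOLERANCE = 1e-8


class NonDifferentiableError(ValueError):
    """Raised when a candidate lacks a derivative the residual needs."""


@dataclass(frozen=True)
class PDEModel:
    """The DNA PDE with (possibly symbolic) parameters.

    Parameters default to the symbols ``alpha``, ``gamma``, ``beta`` so that
    all downstream computations stay fully symbolic unless numbers are
    supplied.
    """

    alpha: sp.Expr = alpha
    gamma: sp.Expr = gamma
    beta: sp.Expr = beta

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma"):
            val = sp.sympify(getattr(self, name))
            if val.is_zero:
                raise ValueError(f"{name} must be nonzero (it appears in denominators)")
            object.__setattr__(self, name, val)
        object.__setattr__(self, "beta", sp.sympify(self.beta))

    @property
    def params(self) -> dict[sp.Symbol, sp.Expr]:
        return {alpha: self.alpha, gamma: self.gamma, beta: self.beta}

    def residual_operator(self) -> sp.Expr:
        """Delta with ``u`` an undetermined function of (z, t)."""
        uf = u(z, t)
        return (
            sp.diff(uf, t, 2)
            - self.alpha**2 * sp.diff(uf, z, 2)
            + self.beta / self.alpha**2 * sp.diff(uf, z, 2, t, 2)
            - self.gamma * sp.diff(sp.diff(uf, z) ** 2, z)
        )

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, object]) -> "PDEModel":
        """Build a model from a config block {alpha, gamma, beta}."""
        kwargs = {}
        for name in ("alpha", "gamma", "beta"):
            if name in cfg and cfg[name] is not None:
                kwargs[name] = sp.nsimplify(sp.sympify(cfg[name]))
        return cls(**kwargs)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular (z, t) sampling grid for numeric residual checks."""

    z_range: tuple[float, float] = (0.0, 1.0)
    t_range: tuple[float, float] = (0.0, 1.0)
    n_z: int = 50
    n_t: int = 50

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        zs = np.linspace(*self.z_range, self.n_z)
        ts = np.linspace(*self.t_range, self.n_t)
        return np.meshgrid(zs, ts, indexing="ij")


@dataclass
class ResidualReport:
    """Symbolic-zero flag plus gridded residual statistics."""

    symbolic_zero: bool
    max_abs_residual: float
    grid_spec: GridSpec
    constraint_set: dict[str, str] = field(default_factory=dict)
    n_excluded: int = 0
    n_evaluated: int = 0
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def numerically_zero(self) -> bool:
        return self.max_abs_residual < self.tolerance

    def to_dict(self) -> dict:
        return {
            "symbolic_zero": self.symbolic_zero,
            "max_abs_residual": self.max_abs_residual,
            "grid_spec": {
                "z_range": list(self.grid_spec.z_range),
                "t_range": list(self.grid_spec.t_range),
                "n_z": self.grid_spec.n_z,
                "n_t": self.grid_spec.n_t,
            },
            "constraint_set": dict(self.constraint_set),
            "n_excluded": self.n_excluded,
            "n_evaluated": self.n_evaluated,
            "tolerance": self.tolerance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _checked_derivative(candidate: sp.Expr, *orders) -> sp.Expr:
    d = sp.diff(candidate, *orders)
    bad = d.atoms(sp.DiracDelta) | {
        a for a in d.atoms(sp.Derivative) if isinstance(a.expr, (sp.Abs, sp.sign, sp.Heaviside))
    }
    if bad:
        name = "u_" + "".join(str(s) * int(n) for s, n in zip(orders[::2], orders[1::2]))
        raise NonDifferentiableError(
            f"candidate is not differentiable: derivative {name} produced {sorted(map(str, bad))}"
        )
    return d


def pde_residual(
    candidate: sp.Expr, model: PDEModel | None = None, do_simplify: bool = True
) -> sp.Expr:
    """Substitute ``candidate(z, t)`` for u in Delta and simplify.

    Returns an identically zero expression exactly when the candidate solves
    the PDE.  The candidate must be four times differentiable in z and twice
    in t; piecewise kinks raise :class:`NonDifferentiableError` naming the
    failing derivative.
    """
    model = model or PDEModel()
    candidate = sp.sympify(candidate)
    u_tt = _checked_derivative(candidate, t, 2)
    u_zz = _checked_derivative(candidate, z, 2)
    u_zztt = _checked_derivative(candidate, z, 2, t, 2)
    u_z = _checked_derivative(candidate, z, 1)
    residual = (
        u_tt
        - model.alpha**2 * u_zz
        + model.beta / model.alpha**2 * u_zztt
        - model.gamma * sp.diff(u_z**2, z)
    )
    return sp.simplify(residual) if do_simplify else residual


def _is_symbolically_zero(expr: sp.Expr) -> bool:
    if expr.is_zero:
        return True
    return sp.simplify(expr) == 0


def numeric_residual(
    candidate: sp.Expr | Callable[[np.ndarray, np.ndarray], np.ndarray],
    model: PDEModel | None = None,
    grid: GridSpec | None = None,
    constraints: Mapping[sp.Symbol, object] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    check_symbolic: bool = True,
) -> ResidualReport:
    """Sample |Delta[candidate]| on a grid and report the maximum.

    Symbolic candidates are differentiated analytically; black-box callables
    are differentiated with 4th-order central finite differences with the
    step tied to the grid spacing.  Grid points where the candidate or the
    residual is singular (non-finite) are excluded and counted; if every
    point is excluded an error is raised.
    """
    model = model or PDEModel()
    grid = grid or GridSpec()
    constraints = dict(constraints or {})
    Z, T = grid.mesh()

    if callable(candidate) and not isinstance(candidate, sp.Expr):
        vals = _finite_difference_residual(candidate, model, constraints, Z, T)
        symbolic_zero = False
    else:
        expr = sp.sympify(candidate).subs(constraints)
        residual = pde_residual(expr, model, do_simplify=check_symbolic)
        residual = residual.subs(constraints)
        symbolic_zero = _is_symbolically_zero(residual) if check_symbolic else False
        f = sp.lambdify((z, t), residual, modules="numpy")
        with np.errstate(all="ignore"):
            vals = np.broadcast_to(np.asarray(f(Z, T), dtype=complex), Z.shape).copy()

    with np.errstate(all="ignore"):
        finite = np.isfinite(vals)
    n_excluded = int(np.size(vals) - np.count_nonzero(finite))
    if not finite.any():
        raise ValueError("all grid points excluded (candidate singular on the whole grid)")
    max_abs = float(np.max(np.abs(vals[finite])))

    return ResidualReport(
        symbolic_zero=symbolic_zero,
        max_abs_residual=max_abs,
        grid_spec=grid,
        constraint_set={str(k): str(v) for k, v in constraints.items()},
        n_excluded=n_excluded,
        n_evaluated=int(np.count_nonzero(finite)),
        tolerance=tolerance,
    )


def _finite_difference_residual(
    candidate: Callable[[np.ndarray, np.ndarray], np.ndarray],
    model: PDEModel,
    constraints: Mapping[sp.Symbol, object],
    Z: np.ndarray,
    T: np.ndarray,
) -> np.ndarray:
    """4th-order central-difference residual for a black-box u(z, t)."""
    subs = {sp.Symbol(str(k), real=True, nonzero=True): v for k, v in constraints.items()}
    a2 = float(sp.sympify(model.alpha**2).subs(model.params).subs(subs))
    g = float(sp.sympify(model.gamma).subs(model.params).subs(subs))
    b = float(sp.sympify(model.beta).subs(model.params).subs(subs))

    hz = (Z.max() - Z.min()) / max(Z.shape[0] - 1, 1) or 1e-3
    ht = (T.max() - T.min()) / max(T.shape[1] - 1, 1) or 1e-3
    # 5-point 4th-order central stencils
    w1 = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
    w2 = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0
    offs = np.array([-2, -1, 0, 1, 2])

    def stencil(f, wz, wt):
        out = np.zeros_like(Z)
        for oz, cz in zip(offs, wz):
            for ot, ct in zip(offs, wt):
                if cz == 0.0 or ct == 0.0:
                    continue
                out += cz * ct * candidate(Z + oz * hz, T + ot * ht)
        return out

    delta = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    u_tt = stencil(candidate, delta, w2) / ht**2
    u_zz = stencil(candidate, w2, delta) / hz**2
    u_zztt = stencil(candidate, w2, w2) / (hz**2 * ht**2)
    u_z = stencil(candidate, w1, delta) / hz
    u_zz_ = u_zz
    # (u_z^2)_z = 2 u_z u_zz
    return u_tt - a2 * u_zz + b / a2 * u_zztt - g * 2.0 * u_z * u_zz_
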