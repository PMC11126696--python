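# dnalie

Symbolic and numeric toolkit for the Lie point-symmetry analysis of the
nonlinear wave equation governing longitudinal strand displacement in DNA
under an external microwave field,

```
u_tt - α² u_zz + (β/α²) u_zztt - γ (u_z²)_z = 0,
```

where `u(z, t)` is the difference in longitudinal displacement between the
two strands, `α` the linear wave speed, `γ` the nonlinear elastic-flux
coefficient and `β` the dispersion coefficient of the fourth-order mixed
term (all dimensionless; `α, γ ≠ 0`).

The package is for researchers in nonlinear waves and continuum
biomolecular dynamics who want the complete solution chain for this model
as *executable, verified* mathematics rather than printed formulas:

* **Symmetry computation** — fourth-order prolongation, determining
  equations within a polynomial ansatz, and their solution. The model
  admits a five-dimensional point-symmetry algebra spanned by time, space
  and displacement translations Y₁ = ∂_t, Y₃ = ∂_z, Y₂ = ∂_u, the boost
  Y₄ = t ∂_u, and the scaling-shear generator
  Y₅ = t ∂_t + (−2u − (α²/γ) z) ∂_u.
* **Algebra structure** — commutator and adjoint tables with symbolic
  α, γ, the Jacobi identity, and a numeric ODE oracle for the adjoint
  series exp(−ε ad Y_m).
* **Optimal system** — the ten published one-dimensional subalgebra
  representatives Λ₁…Λ₁₀, with every printed adjoint-cancellation step
  replayed and validated (solving for the group parameters the derivation
  leaves implicit); steps that cannot hold are recorded as discrepancies.
* **Similarity reductions** — invariant variables σ(z, t), solution forms
  u = P(z,t) + W(z,t) h(σ) and the reduced ODEs for every reducible class,
  matched against the published equations up to a recorded nonzero factor.
* **Closed-form invariant solutions** — quadrature of the reducible ODEs
  and assembly of the seven published invariant solutions, each verified to
  symbolic PDE residual zero.
* **Auxiliary-equation traveling waves** — the Riccati-form auxiliary
  equation F′ = g₂F² + g₁F + g₃, degree balancing, the algebraic
  coefficient solve, the 17-case solution catalogue with honest
  exact/repaired classification against a canonical Riccati oracle, and the
  24 labelled traveling waves u₁…u₂₄ (σ = t − z) verified end to end.
* **Numeric lab** — guarded integration of the two reductions that resist
  quadrature, and sampling of the six published displacement-profile
  figures at their caption parameter values.

## Worked example

Solve the determining equations and print the symmetry algebra:

```bash
$ dnalie symfind
{
 "dimension": 5,
 "generators": [
  "(1)*d/dz",
  "(1)*d/dt",
  "(1)*d/du",
  "(t)*d/du",
  "(-t/2)*d/dt + ((alpha**2*z + 2*gamma*u)/(2*gamma))*d/du"
 ]
}
```

The five solved generators span exactly the algebra above (the last one is
−Y₅/2, a basis choice; span equality is what the tests assert).  Reduce
along the class Λ₇⁺ = Y₁ + Y₄:

```bash
$ dnalie reduce --label Lambda7+
{
 "form": "t**2/2 + h(sigma)",
 "ode": "alpha**2*Derivative(h(sigma), (sigma, 2)) + 2*gamma*Derivative(h(sigma), sigma)*Derivative(h(sigma), (sigma, 2)) - 1",
 "sigma": "z"
}
```

i.e. u = t²/2 + h(z) with 2γh′h″ + α²h″ − 1 = 0, whose quadrature gives the
3/2-power invariant solution; `dnalie invariants` assembles and verifies
it.  In Python:

```python
>>> from dnalie import PDEModel, pde_residual, invariant_solution_catalog
>>> cat = invariant_solution_catalog()
>>> sol = cat["Lambda7+"]          # the boost-invariant 3/2-power solution
>>> sol.verified                   # symbolic PDE residual is identically 0
True
>>> pde_residual(sol.expression)
0
```

`dnalie aux-verify` classifies each of the 24 printed catalogue branches
against the Riccati oracle; `dnalie aux-solve --mode consistent` emits the
24 repaired traveling waves, all of which verify to residual zero, and
`--mode as_printed` keeps the published formulas verbatim for
figure reproduction (`dnalie simulate --figure 3`).  `dnalie pipeline`
runs every stage and writes a JSON/CSV report bundle.

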