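# Methods

## The model

The package analyses the nonlinear dispersive wave equation

    Δ ≡ u_tt − α² u_zz + (β/α²) u_zztt − γ (u_z²)_z = 0

for the longitudinal displacement difference u(z, t) between the two
strands of a DNA double helix driven by a microwave field.  All three
parameters are dimensionless reals; α (wave speed) and γ (nonlinear flux)
must be nonzero because they appear in denominators of the invariant
solutions, while β (dispersion) may vanish, in which case the equation is
second order.  The residual Δ is stored exactly in the form above and is
never rescaled; every downstream "matches up to a factor" statement
records its factor relative to this normalization.

A note on symbols: the source literature writes the dispersion
coefficient as ϑ₃ and *also* uses ϑ₁, ϑ₂, ϑ₃ for the auxiliary-equation
catalogue parameters.  The package renames the PDE coefficient to β and
keeps θ₁, θ₂, θ₃ for the catalogue, so the two never collide.

## Symmetry computation

Point symmetries are vector fields Y = ξ_z ∂_z + ξ_t ∂_t + η ∂_u whose
fourth prolongation annihilates Δ on the solution manifold.  The jet-space
machinery uses the standard total-derivative recursion
η^{J,k} = D_k η^J − (D_k ξ_z) u_{J,z} − (D_k ξ_t) u_{J,t}; the recursion
path (extend in z first, then t) is fixed, and path-independence is tested
against the characteristic-formula oracle η^J = D^J Q + ξ_z u_{J,z} +
ξ_t u_{J,t} with Q = η − ξ_z u_z − ξ_t u_t.

On-shell reduction eliminates u_zztt, which enters Δ linearly with
constant coefficient β/α².  The resulting expression is cleared of the
nonzero factors α², β and split on monomials in the remaining jet
coordinates and in (z, t, u).

The determining equations are solved within a polynomial coefficient
ansatz (default total degree 2 in (z, t, u); degrees 1 and 3 are exercised
in the tests).  The solution space has dimension 5 at every tested degree,
so the claim "no further symmetries" is asserted only within those ansatz
degrees — the general determining equations are not solved in closed form
here.  Basis vectors are only defined up to linear combination; span
comparisons reduce both bases to row-echelon form over an ordered
(z, t, u)-monomial list.

## Algebra structure and the optimal system

The commutator convention is [X, Y] = X(Y) − Y(X) on coefficient
functions, which reproduces [Y₁, Y₄] = +Y₂.  Structure constants are
rational in α, γ; antisymmetry and the Jacobi identity hold identically.

Ad(e^{εY_m}) is computed by summing the ad-series termwise up to 12 terms;
for the nilpotent generators the series terminates and the partial sum is
exact, for Y₅ the matrix exponential is used and verified against the
defining linear ODE dW/dε = −[Y_m, W].  A numeric solve_ivp oracle
cross-checks the closed forms to 1e−8 in the tests.

The one-dimensional optimal system is the published ten-class list; the
package does not re-derive an optimal system by invariant-based
classification (a stated non-goal).  Instead, every printed
adjoint-normalization step is *replayed*: the claimed zero components are
solved for ε on the true adjoint action and the outcome is compared with
the printed one, exactly and up to an overall scalar (one-dimensional
subalgebras being defined up to scale).  The replay records, rather than
repairs:

* Case 1/2, first step: a single Y₁-action cannot annihilate both the Y₁
  and Y₂ components (the printed intermediate drops k₂ prematurely; a
  later Y₃- or Y₂-action absorbs it, and the corrected sequences in
  `normalize_to_representative` do exactly that).
* Case 3: the printed Ad(e^{εY₅}) step claims an e^{−4ε} rescaling of the
  Y₃ component and silently drops Y₄; in fact the Y₃ component is inert
  under ad(Y₅) up to a Y₂ shear and no ε annihilates e^{−3ε}k₄.  Moreover
  the class Y₁ + aY₃ ± Y₄ carries a genuine modulus on a that the two
  available group parameters cannot normalize to ±1.
* Cases 4/5: the Y₅-scaling reintroduces a Y₂ component through
  Ad(e^{εY₅})Y₃ = Y₃ + (α²/2γ)(e^{−2ε}−1)Y₂ that the printed intermediates
  omit (it is removable afterwards, so the final representatives stand).
* Case 6: the Y₂ absorption ε = −log(r)/2 with
  r = (α²k₃/2γ)/(k₂ + α²k₃/2γ) exists only for r > 0; the ray
  k₂ = −α²k₃/(2γ) is a fixed point of the only nontrivial adjoint action
  and is a representative the published list does not contain.

## Similarity reductions

For every generator in the algebra, ξ_z is constant, ξ_t is affine in t
and η is affine in u, so the characteristic system is solved in closed
form.  The integration convention — integrate the u-equation along z when
ξ_z ≠ 0 (eliminating t through σ), otherwise along t at fixed z, with the
additive constant becoming h(σ) scaled by the homogeneous solution W —
reproduces the published similarity variables and solution forms verbatim
for all reduced classes.  Substituting u = P + W·h(σ) into Δ, rewriting in
(σ, τ) coordinates, and dividing out the h-free denominator and the common
content yields the canonical reduced ODE (highest derivative with positive
leading coefficient); the dropped factor is stored.

Both reductions the source leaves to numerics recompute *exactly*: the
scaling reduction equals α²t⁴·Δ and the forced fourth-order reduction
equals α²·Δ, so the agreement report records exact matches (factors −1/2
and 1 against the package's canonical normalization).

Closed-form integration covers the shape A h′h″ + B h″ + C = 0 with
constant A, B, C: for C = 0 the equation factors (one linear branch, one
constant-slope branch); otherwise the first integral (A/2)h′² + Bh′ + Cσ =
const gives two square-root branches whose integrals are the 3/2-power
solutions.  The radicand's nonnegativity is attached as a domain
constraint instead of being assumed, and both branches are verified —
the published list prints one branch per class, but the second also solves
the PDE.  Free constants are relabelled (c₁ ↦ −c₁ where needed) so the
stored solutions diff cleanly against the printed ones.  β drops out of
every closed-form invariant solution because no fourth derivative
survives.

## The auxiliary-equation method

The auxiliary ODE h′ = (1/ln Θ)(Γ₁ + Γ₂Θ^h + Γ₃Θ^{−h}) becomes, under
F = Θ^h, the Riccati equation F′ = g₂F² + g₁F + g₃ with
(g₁, g₂, g₃) = (Γ₁, Γ₂, Γ₃); the base Θ drops out, and this Riccati form
is the single internal convention.  Balancing on the traveling reduction
βh⁗ − α²(α² − 2γh′ − 1)h″ = 0 gives k = 1 for h directly and k = 2 for
the once-integrated equation in w = h′; the degree-2 ansatz is solved
anyway, and the algebra itself forces the quadratic coefficient to zero
(the top F⁷ coefficient of the nonlinear term cannot cancel), so the
surviving family is linear in F:

    b₁ = 6 g₂ (α² − 1) / (γ (4 g₂ g₃ − g₁²)),
    β  = α² (α² − 1) / (g₁² − 4 g₂ g₃).

The published coefficient set has the same 6/4 structure with the roles of
the linear and quadratic Riccati coefficients exchanged (consistent with
reading the auxiliary ODE as F′ = Γ₁F² + Γ₂F + Γ₃) and the opposite sign
on β; the comparison report stores both, with provenance tags.  The
published waves square their bracket (u = b₀ + B·F²), which the derivation
above rules out as a solution family; consistent mode therefore emits
u = b₀ + b₁F over the repaired catalogue entries, while as_printed mode
keeps the squared forms verbatim for figure reproduction.  Both modes emit
one wave per printed branch — 24 labelled waves.

Catalogue verification is honest classification, not assumption: each of
the 24 printed branches is tested against the Riccati form with θᵢ ≡ Γᵢ.
Where the branch is rational in a single transcendental kernel (tan, cot,
tanh, coth, exp with σ-linear argument) the kernel is replaced by a symbol
with its derivative closure and the residual is decided exactly by
rational cancellation; the square-root-of-exponential branch (Case 8)
falls back to a 50-digit numeric sample at parameter draws satisfying the
case condition.  All printed branches fail as printed (the catalogue
follows a systematic half-argument convention, and several amplitudes are
reciprocal to the canonical ones); one branch (Case 16) equals the
canonical solution under σ → 2σ, and the Case 13 branch is exact under the
alternative reading F′ = θ₃F² + 2θ₁F + θ₂.  Every case gets a canonical
repaired solution of the same function family (tan/cot for negative
discriminant, tanh/coth for positive, rational for zero, exponential for
the linear degenerations), and every repaired form verifies exactly.
Derived validity conditions come from the sign of the discriminant
g₁² − 4g₂g₃ of the constrained coefficients and are used for
verification; the printed conditions (including the duplicated Case 2/3
condition) are stored verbatim, unresolved.

Two degenerate cases (11 and 14) have vanishing quadratic Riccati
coefficient under their constraints; there the expansion collapses to the
constant solution, which is emitted as a flagged degenerate wave rather
than silently dropped.

End-to-end wave verification is factored into two exact steps — the
ansatz solves the traveling ODE modulo the Riccati closure (a polynomial
identity in F), and the wave's F solves the closure (kernel-exact) — plus
a complex-aware numeric grid residual.  The wave residual is independent
of b₀ by construction, and the tests assert it.

## Numerics

The scaling reduction is integrated as h″ = −6α²h/(6β − 2α²γh′) with a
terminal event at |6β − 2α²γh′| < 1e−6 (the moving mass term), the forced
fourth-order reduction as a dimension-4 first-order system; both use RK45
at rtol 1e−10 / atol 1e−12.  Initial conditions are required inputs with
small-perturbation defaults (h = 0.1, derivatives 0) — the source states
none, and the package does not guess that its figures came from any
particular choice.  The along-path residual is recomputed from derivatives
of the dense interpolant (a small central difference), i.e. not from the
right-hand side used during stepping; self-consistency under tolerance
halving is asserted at 1e−6 in sup-norm.

Figure profiles evaluate the cited closed forms at the caption bindings,
verbatim, over a configurable z-window (default [−10, 10], 401 points).
Expressions are rewritten in exponential form so trig/hyperbolic poles
stay visible in a denominator; a point is masked when the denominator
falls below 1e−6 of its median magnitude over the window, or the value is
non-finite.  Complex values are reported as real part plus imaginary
magnitude.  Findings from the as_printed surface: the caption of the
"periodic" figure sets α = 1, which makes the printed amplitude factor
α² − 1 vanish (the printed u₁ is constant there); the dark-soliton and
singular figures set θ₂ = θ₃ = 1 so √(−θ₂θ₃) is imaginary, yet the
evaluated waves are real because tanh(ix) = i tan(x) — they are periodic
tan²-type profiles under those bindings, with the singular figure's pole
masked.

## Fixtures and determinism

Seeded fixtures (numpy PCG64) provide nonzero rational parameter draws
with α ≥ 1/2, random degree-2 polynomial vector fields as negative
controls (generic fields are not symmetries), and Riccati triples
stratified by discriminant sign (zero-discriminant triples are
constructed, since they have measure zero).  The pipeline writes JSON with
sorted keys and no timestamps; identical config and seed give
byte-identical bundles, which the tests check.

## Known limitations

* "No further symmetries" is established only within polynomial ansatz
  degrees ≤ 3, not in general.
* The optimal system is validated and its gaps documented, but no
  replacement classification is derived (stated non-goal).
* The PDE itself is never time-stepped (stated non-goal); all numeric work
  is on the reduced ODEs and on closed-form evaluation.
* Quadrature handles the constant-coefficient first-integral shape that
  actually occurs; other reduced ODEs are routed to the numeric lab
  explicitly.
* The synthetic fixtures exercise algebraic properties; they are not
  simulations of physical DNA data, and passing tests say nothing about
  the biological fidelity of the model itself.
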