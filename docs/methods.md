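# Methods

## Model

Five compartments (V potential smokers, G occasional smokers, T smokers,
O temporary quitters, W permanent quitters) with a fractional time
derivative D^μ of order μ ∈ (0,1]. Rates, all per unit time unless noted,
with package defaults:

| parameter | meaning | default |
|---|---|---|
| α | recruitment rate into V | 1 |
| ε | effective V–T contact rate | 0.14 |
| ϑ | natural death rate (all compartments) | 0.05 |
| ρ | quit rate of smokers | 0.8 |
| σ | fraction of quitters who quit permanently (dimensionless, [0,1]) | 0.1 |
| ε₁ | occasional → regular transition rate | 0.002 |
| ε₂ | relapse contact rate between T and O | 0.0025 |
| initial (V,G,T,O,W) | compartment counts at τ=0 | (40, 10, 20, 10, 5) |

The compartment total N = V+G+T+O+W obeys D^μN = α − ϑN exactly: all
contact and transfer terms cancel. The solver tests exploit this as a
conservation identity at every series level.

## Series solver

The solution is expanded as x_i = Σ_{k=0}^{K} x_{i,k}. Level 0 is the
initial value; level k+1 applies the kernel's inverse-transform operator to
the level-k right-hand side (constants + linear terms + level-k Adomian
convolutions of the bilinear terms). The integral transform underlying the
method is applied and inverted analytically — never numerically — which
reduces each kernel to a term-wise map on monomials c·τ^p:

* power-law kernel (Caputo): c·Γ(p+1)/Γ(p+μ+1)·τ^(p+μ);
* exponential kernel (Caputo–Fabrizio): (1−μ)c·τ^p + μc/(p+1)·τ^(p+1);
* Mittag–Leffler kernel (Atangana–Baleanu–Caputo):
  [(1−μ)c·τ^p + μc·Γ(p+1)/Γ(p+μ+1)·τ^(p+μ)]/B(μ).

All components therefore live in the closed family Σ c·τ^(a+bμ) with
nonnegative integers a, b. Exponents are stored as exact integer pairs —
never floats — so exponential-kernel terms (integer shifts) and
power-law/Mittag–Leffler terms (μ shifts) coexist without spurious merging
at special values of μ. Coefficients are doubles; gamma ratios are
evaluated via log-gamma. Evaluation sums terms in ascending numeric
exponent (ties by (b,a)) for reproducibility; the solver is fully
deterministic.

### Source-term convention

Two conventions exist for the constant source α in the recursion:

* `source_mode="every_level"` (default): α is included in the right-hand
  side of **every** level k ≥ 0. This is the convention under which the
  package reproduces the reference comparison tables; it introduces an
  extra α·τ^μ/Γ(1+μ) term at level 2 and beyond.
* `source_mode="first_level"`: α enters only at level 0, the textbook
  decomposition convention. At μ = 1 this makes the K-term partial sum the
  exact degree-K Maclaurin polynomial of the classical solution, and the
  truncation error scales as τ^(K+1) (verified: log–log slope 2.97 for
  K = 2) and as τ^((K+1)μ) at fractional order (slope 2.34 at μ = 0.8,
  target 2.4).

Convergence-order tests use `first_level`; table reproduction uses
`every_level`.

### Defaults and ranges

* Truncation order K = 2 (three components), the order at which the
  comparison tables are generated; configurable upward (term count grows
  polynomially, K ≲ 10 is instantaneous).
* B(μ) = 1 for the Mittag–Leffler normalization. Any positive value is
  accepted, but the reference series carry no normalization prefactor,
  which pins B = 1; it is exposed as a configuration field.
* No magnitude-based pruning of coefficients: only exact zeros are dropped.
* A truncation diagnostic reports |last component| / |partial sum| per
  state and τ and flags grid points where this exceeds 5 % (configurable);
  it is an empirical convergence check — the series is asymptotic in τ and
  partial sums degrade beyond τ ≈ 0.5 at these rates.

### Behaviour at τ = 0

The power-law kernel's operator maps every monomial to a strictly positive
power, so Caputo partial sums equal the initial values at τ = 0. The
exponential and Mittag–Leffler operators carry a (1−μ)·identity part, so
for μ < 1 their partial sums are shifted at τ = 0 (e.g. V(0) = 34.17
instead of 40 at μ = 0.8, K = 2). This is a property of the method as
defined, not a defect of the implementation, and it matches the reference
tables' τ = 0 rows.

## Reproduction number and equilibria

The next-generation construction gives the eigenvalue

    λ = R₀ = ε₁ ε ϑ V / [(ε₁+ϑ)(ϑ+ρ)(ϑ+εT)]

with V and T left free; they default to the initial values (40, 20), the
point at which the headline stability statement evaluates them (λ ≈
0.00445 < 1, smoking-free state locally asymptotically stable). The
sensitivity partials ∂R₀/∂ε₁, ∂R₀/∂ε, ∂R₀/∂ρ, ∂R₀/∂ϑ are obtained by
direct differentiation of this expression (the ϑ-partial via the
log-derivative, since ϑ enters all four factors) and each is cross-checked
against a central finite difference at relative tolerance 1e-6. At the
default rates the robust directions are: R₀ increases with ε₁ and ε,
decreases with ρ; the ϑ-partial is negative at the defaults but its sign is
parameter-dependent and is reported, not asserted.

The smoking-free equilibrium is (α/ϑ, 0, 0, 0, 0). The endemic branch
expresses V*, G*, O*, W* in closed form as functions of the smoker level T
and solves the remaining scalar consistency equation
ε₁G*(T) + ε₂T·O*(T) − (ϑ+ρ)T = 0 for T > 0 by bracketed root-finding
(scan for a sign change of the equation divided by T on a geometric grid,
then Brent's method, xtol 1e-12). With the default rates no positive root
exists — permanent quitting drains the smoking classes — and the endemic
entry is reported absent rather than raising. Reported equilibria are
plugged back into the right-hand side; the residual must be ≤ 1e-8.

## Reference oracles

* Classical fixed-step RK4 — ground truth at μ = 1. Fourth-order
  self-consistency verified by Richardson halving.
* Fractional Adams–Bashforth–Moulton predictor–corrector (PECE, one
  correction per step, product-rectangle predictor and product-trapezoidal
  corrector weights) — independent Caputo solver for μ < 1. Validated
  against RK4 at μ = 1 (≤1e-5 at τ=0.1, h=1e-4) and against the converged
  Mittag–Leffler series of the scalar linear problem D^μx = −x (≤1.2e-7
  at h = 2.5e-4). The scheme is O(N²) in step count; tests use
  h ∈ [1e-5, 2.5e-4] on horizons ≤ 0.5, a few seconds at most.

These oracles share no code with the series solver and are used only for
verification, never as the solution path.

## Scope and limitations

* Nonlinearities are restricted to bilinear products; general Adomian
  polynomials for non-polynomial nonlinearities are out of scope.
* The ABC kernel never requires Mittag–Leffler function evaluation at run
  time: its action on monomials closes via gamma ratios.
* Symbolic-μ coefficients (a CAS mode), μ > 1, Riemann–Liouville
  derivative variants, Padé acceleration, and parameter estimation from
  prevalence data are not implemented.
* Comparison-table columns for external methods (LADM, q-HATM) are emitted
  as empty placeholders: they are other solvers' published values.
* The truncated series is accurate only near τ = 0; for long horizons use
  the numeric integrators or restart strategies (not implemented).
* The classical-order G column of the published comparison grid and one
  fractional-order block of the temporary-quitter grid are internally
  inconsistent with the recursion that generated the rest (the computed G
  values instead match the published LADM column); those cells are
  excluded from the quantitative checks and documented in the tests.
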