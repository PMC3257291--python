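# Methods

## Model class and assumptions

`stocan` analyzes reaction networks treated as continuous-time Markov jump
processes on molecule counts (counts are dimensionless; any volume factor is
absorbed into the rate constants, so "concentration" and "count" coincide).
A network is species + strictly positive parameters + reactions, each
reaction carrying an integer net stoichiometry and a rate-law expression
over species/parameter identifiers.  The expression grammar is deliberately
small — `+ - * / ^`, parentheses, numeric literals, and a built-in
`hill(x, K, h) = 1/(1+(x/K)^h)` inhibition term — so that every admissible
rate law is totally differentiable by the symbolic layer (sympy); anything
outside the grammar is a schema error rather than a silent fallback.
Boundary species hold fixed amounts: they may appear in rate laws (constant
enzymes) but have no stoichiometry row and no fluctuations.

Langevin-kind networks reuse the same drift (stoichiometry × rates) but
carry an explicit, constant, symmetric diffusion matrix over their dynamic
species.  They model systems (like the damped p53-style oscillator) where
noise is supplied as additive Gaussian forcing rather than reaction shot
noise.  Langevin networks with conservation relations are rejected — none of
the intended models need them and the reduction bookkeeping would be
untested code.

All second-moment statements are made at the level of the linear noise
approximation (LNA): fluctuations are assumed small enough that rate laws
can be linearized about the deterministic steady state.  The LNA is exact
for networks whose rates are affine in the state (birth-death, the
two-state promoter, the metabolic chains here) and an approximation
otherwise; the package's SSA module exists precisely to check it case by
case.

## Stoichiometric reduction

Conservation relations (e.g. total promoter copies) make the full-space
Lyapunov equation singular, so all covariance work happens in an
independent-species subspace.  The factorization `N = L·N_R` picks
independent species by a greedy scan of the rows of `N` in declaration order
(first maximal independent set), using exact rational arithmetic; `L` is
solved exactly and verified, and each dependent species yields a
conservation row `g` with `g·N = 0` and total `g·x₀`.  Determinism of this
choice is a contract: the same model text always produces the same matrices.

## Steady state and second moments

* Steady state: damped Newton (line search on the residual norm, step
  halving, non-negativity guard) on `N_R·v(x(ξ)) = 0` in independent
  coordinates, with an LSODA relaxation fallback followed by a Newton
  polish.  Convergence demands `‖N_R v‖ < 1e-10·max(1, ‖v‖)`; conservation
  totals are preserved exactly by construction.  The tolerance is this
  package's choice.
* Linearization: `A = N_R (∂v/∂x) L`; for jump networks
  `D = N_R diag(v*) N_Rᵀ` (each reaction injects shot noise at its
  stationary flux); for Langevin networks `D` is the model's matrix.
* Covariance: dense Schur-based Lyapunov solve
  (`scipy.linalg.solve_continuous_lyapunov`); networks of interest are at
  most dozens of species.  `A` must be Hurwitz, else a stability error.
  The residual must stay below `1e-10·‖D‖`, the covariance is symmetrized,
  and eigenvalues below `−1e-9` (relative) are an error rather than being
  clipped.
* Autocorrelation: `R(τ) = e^{Aτ} C` by matrix exponential on the lag grid
  (reference route) with an ODE-integration route (`dR/dτ = A·R`) as a
  cross-check; the two agree to solver accuracy in the tests.  Normalized
  same-species curves are `A_ii(τ) = R_ii(τ)/C_ii`.

## Control coefficients

Scaled CCs are log-log derivatives `(p/Y)∂Y/∂p`, which is why parameters
must be positive.  The pipeline is fully analytic:

1. mean CCs from the MCA formula `−L M⁻¹ N_R ∂v/∂p`, `M = N_R (∂v/∂x) L`
   (an ill-conditioned `M` is reported as a degenerate steady state);
2. per-parameter total derivatives `δA`, `δD` combining explicit dependence
   with the implicit shift through `dx*/dp`;
3. `δC` from the Sylvester-type equation `A δC + δC Aᵀ = −(δA C + C δAᵀ + δD)`;
4. noise CCs by the quotient rule on `η = C/(x xᵀ)`;
5. autocorrelation sensitivities by one block matrix exponential of
   `[[A, 0], [δA, A]]` per (parameter, lag), applied to `[C; δC]`.

Second derivatives of the rate laws (needed in `δA`) are computed
symbolically.  The grammar keeps symbolic differentiation total at any
order, and an exact analytic route makes the Richardson behaviour of the
finite-difference comparison clean: the measured analytic-vs-oracle gap is
pure oracle truncation error and shrinks 4× when the oracle step halves.

The independent oracle (`finite_difference_ccs`) recomputes the *entire*
pipeline (steady state → Lyapunov → η or autocorrelation) at parameters
`p(1 ± step)` and central-differences the results; it shares no code path
with the analytic derivatives beyond the forward model itself.

Scaled CCs are undefined where the underlying quantity vanishes (zero
covariance entries, autocorrelation magnitudes below 1e-6); those slots are
reported as NaN with the unscaled value retained, rather than inventing a
number.

Two structural identities serve as permanent oracles: (i) summation
theorems — uniform rescaling of all rate constants only rescales time, so
scaled mean and noise CCs sum to zero over the rate-parameter set, and
autocorrelation CCs sum to `τ d(ln A)/dτ`; (ii) Poisson anti-parallelism —
open first-order networks have product-form Poisson stationary laws
(`C = diag(x*)`), hence noise CCs exactly equal to the negated mean CCs.

## Control design

Designs live in relative parameter space: a direction `û` is applied as
`p_j ← p_j(1 + λû_j)`, which pairs with scaled CCs and keeps parameters
positive for small λ.

* Orthogonal design: direction `∓` the normalized projection of the moved
  vector off the fixed vector.  Efficiency is `|sin θ|`, computed from the
  projection norm rather than `arccos`→`sin` round-tripping, so exactly
  (anti-)parallel vectors give exactly 0 (the angle route loses eight
  digits there).  `ε < 1e-10` is reported as an "impossible" outcome with
  `S = 0`, not an exception.  The projection is equivalent to the
  minimum-norm Lagrange solution of the constrained problem; the test suite
  verifies cosine similarity `> 1 − 1e-10` on random instances.
* Generalized design: pseudoinverse minimum-norm solve; a least-squares
  residual above `1e-8·‖targets‖` (configurable) marks the request
  overconstrained.
* Constraint tolerance: the admissible set widens from the perpendicular
  hyperplane to a cone of half-angle `θ_d = arcsin(min(1, tol/‖G_fixed‖))`.
  With `α` the angle between the moved vector and the hyperplane (computed
  by `arctan2` of the projection split, for precision at both ends),
  efficiency becomes 1 for `α ≤ θ_d` (boundary resolved in favor of 1) and
  `cos(α − θ_d)` otherwise; `tol = 0` reproduces the plain design exactly,
  and efficiency is non-decreasing in `tol`, reaching 1 at
  `tol ≥ ‖G_fixed‖`.  This cone geometry is the package's reconstruction of
  "allow the fixed variable to move by at most `tol` per unit
  perturbation"; its limiting cases pin it down uniquely up to the boundary
  convention.
* Pair ranking enumerates all unordered parameter pairs in their 2-D
  restrictions; a pair where only the fixed vector vanishes is maximally
  efficient (`ε = 1`), one where the moved vector vanishes scores 0.
* Iterative reduction recomputes the design at every step (first-order
  Euler along the flow).  Step size λ = 0.05 and 5 iterations are defaults,
  not recommendations; the trace records parameters, mean and noise at each
  step and halts with a partial trace on lost stability or positivity.
* Oscillation scoring anchors on the first trough `τ₁` and following peak
  `τ₂` of the normalized autocorrelation (amplitude), and on the steepest
  falling flank before the trough plus the steepest rising flank after it
  (period).  A parameter scores for amplitude when its scaled CCs at
  `τ₁, τ₂` share a sign — the autocorrelation is negative at the trough, so
  same-sign *scaled* CCs mean the trough deepens while the peak rises —
  and for period when the flank CCs have opposite signs.  Anchors are found
  automatically from the curve's extrema rather than chosen by eye.

## Simulation and estimators

The SSA is the plain direct method (no tau-leaping): fixtures are small and
exactness is the point.  One seeded generator per trajectory; the seed is
recorded in the output.  Langevin paths use Euler–Maruyama with a PSD
square root of `D`; the discrete chain's stationary variance for the linear
test problem is `D/(2a − a²Δt)`, and the estimator tests check the measured
variance against that biased value, which documents the O(Δt) weak bias
concretely.

Stationary estimates resample the post-burn-in segment (default burn-in
20%) — sample-and-hold for jump paths, native uniform samples for Langevin
paths (interpolating between Euler steps would deflate the variance) — and
derive standard errors from 32 contiguous batch means; below 20 batches the
SEs are reported missing.  Autocorrelation lags are snapped to the
resampling grid and the snapped lags are reported.

## Fixture defaults and what the tests show

Fixture parameters are this package's documented choices (units: one
consistent time unit throughout; counts dimensionless):

* birth-death: `k_s = 2, k_d = 0.4` → mean 5, noise level 0.2;
* two-state promoter: `k_on = 0.1, k_off = 0.9, k_tx = 10, d_m = 1,
  k_tl = 5, d_p = 0.1`, one promoter copy → bursty expression (protein
  noise level ≈ 0.89, far above the Poisson floor 1/50 = 0.02);
* metabolic chain: `k1 = 1, k2 = 2, k3 = 1.5, k4 = 1`, enzyme level 10;
  feedback variant adds `hill(X3, K=10, h=2)` on the first step; the
  extrinsic-noise variant gives the enzyme birth-death dynamics
  `a_e = 1, d_e = 0.1` (same mean level 10);
* feedback oscillator: `β_a = 10, d_a = 0.1, k_pa = 0.2, β_p = 1,
  d_p = 0.1, k_mp = 0.5, β_m = 2, d_m = 0.1`, unit diffusion — chosen for a
  clearly underdamped Jacobian (eigenvalues −0.1 ± 1.1i), giving an
  autocorrelation trough of −0.75 near lag 2.8 and a peak of +0.57 near
  lag 5.7.  Construction fails loudly if a parameter override makes the
  eigenvalues purely real.

These fixtures emulate the *structure* of the motivating systems (bursty
promoters, end-product-inhibited chains, delayed negative feedback), not
any measured organism: passing tests demonstrate the mathematics and the
implementation, and the qualitative structure–controllability conclusions
(Poisson networks are uncontrollable; feedback or extrinsic noise restores
controllability; translation-type parameters dominate promoter noise/mean
trade-offs), but no quantitative claim about a specific biological system.
Real gene-expression data additionally contain extrinsic noise sources,
cell-cycle effects and measurement noise that none of these models carry.

On the metabolic fixtures, the end-product mean depends on the chain
constants only through `k1/k4`, and the orthogonal direction moves `k1` and
`k4` by a common factor, so the "fixed" mean is exactly invariant along the
iterative flow — stronger than the generic O(λ²)-per-step guarantee.  The
Euler drift order is therefore measured on the two-state promoter, whose
protein mean has genuine curvature along the flow (observed: halving λ at
fixed step count reduces the drift ≈ 3.9×).

## Problem sizes

Default analysis runs solve systems of at most a handful of species, so the
whole CC pipeline is milliseconds.  The verification simulations use about
10⁶ reaction events per network (e.g. `t_end = 2×10⁵` for the birth-death
process), enough to resolve LNA agreement at the 3-SE level with 32 batch
means.

## Known limitations

* Sensitivities are infinitesimal: large finite perturbations (10× changes,
  promoter mutations) can disagree with CC-based predictions; the iterative
  protocol mitigates but does not remove this.
* No frequency-domain (power-spectral-density) control coefficients; the
  autocorrelation route was chosen because it needs no matrix inversion.
* Moments above second order are out of scope, as are events, delays,
  dynamic compartments, and hybrid simulation.
* Cross-species autocorrelation CCs are computed unscaled only.
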