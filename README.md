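# stocan — stochastic control analysis of reaction networks

Cell-to-cell variability in molecule numbers ("noise") is a phenotype in its
own right: it sets switching rates between gene-expression states, degrades
metabolic flux, and drives noisy oscillations such as the p53–Mdm2 damage
response.  `stocan` is a toolkit for *designing* parameter perturbations that
reshape this noise — for example, lowering a protein's noise level while
holding its mean fixed — in any reaction network modeled as a continuous-time
Markov jump process (or a chemical Langevin system).

It is aimed at systems/synthetic biologists and modelers who have a
rate-law model of their network and want to know **which parameters to
perturb, in which ratio, and what that buys them**.

## The method

For a network with stoichiometry `N = L·N_R` (link matrix `L`, reduced
full-row-rank `N_R` over independent species) and rates `v(x, p)`, the
linear noise approximation (LNA) gives the stationary covariance `C` from
the Lyapunov / fluctuation–dissipation equation

    A·C + C·Aᵀ + D = 0,   A = N_R (∂v/∂x) L,   D = N_R diag(v*) N_Rᵀ,

noise levels `η_ij = C_ij/(x*_i x*_j)` (squared coefficient of variation on
the diagonal), and lagged covariances `R(τ) = e^{Aτ} C`.

**Control coefficients (CCs)** are the scaled sensitivities
`C^Y_p = (p/Y) ∂Y/∂p` of any stationary property `Y` (mean, noise level,
normalized autocorrelation at lag τ) to each parameter.  Mean CCs follow the
classical metabolic-control-analysis formula
`∂x*/∂p = −L (N_R J L)^{-1} N_R ∂v/∂p`; second-moment CCs come from
differentiating the Lyapunov equation along `p`; autocorrelation CCs from
the variational system `d(δR)/dτ = A·δR + δA·R`.  Because a uniform
rescaling of all rate constants only rescales time, the scaled CCs of means
and noise levels sum to zero over all rate parameters (summation theorems) —
a built-in correctness oracle.

**Control design** works in relative parameter space (`δp_j/p_j`):

* *Orthogonal control*: project the noise-level control vector `G_η` onto
  the hyperplane perpendicular to the mean control vector `G_μ`.  Moving
  along the (sign-flipped) projection reduces the noise while leaving the
  mean unchanged to first order.  Efficiency `ε = |sin θ|` (θ the angle
  between `G_μ` and `G_η`) and strength `S = ‖G_η‖·ε`.  For species with a
  Poisson stationary law the two vectors are anti-parallel, `ε = 0`, and
  orthogonal control is impossible — feedback or extrinsic noise restores it.
* *Generalized control*: minimum-norm `δp/p` achieving several % changes at
  once, via the pseudoinverse of the stacked control vectors (equivalently a
  Lagrange-multiplier construction); inconsistent targets are reported as
  overconstrained.
* *Constraint tolerance*: if the mean is allowed to move by `tol` per unit
  perturbation, the admissible set widens to a cone of half-angle
  `θ_d = arcsin(min(1, tol/‖G_μ‖))` and `ε` is re-evaluated against it.
* *Iterative noise reduction*: repeat design → small multiplicative update
  `p ← p(1 + λû)`; a first-order Euler scheme whose fixed-mean drift is
  O(λ²) per step.
* *Oscillation control*: rank parameters by their autocorrelation CCs at
  the trough/peak (amplitude: same-sign CCs) and at the steepest flanks
  (period: opposite-sign CCs).

Exact Gillespie simulation (and Euler–Maruyama for Langevin models) verifies
any design against the LNA predictions.

## Worked example

The bursty two-state promoter (gene toggling between inactive/active states,
transcription only when active) at the package defaults has protein noise
level η ≈ 0.89.  Which two parameters reduce it without moving the mean?

```sh
$ stocan rank-pairs --fixture two_state_promoter --species protein --tol 0.05
parameters,efficiency,strength
k_on+k_tl,0.7540364534949455,0.8064338960091348
k_tl+d_p,0.713924458541562,0.6236204834116853
k_on+d_m,0.7108933651266002,0.7628402236485308
...
```

The best pair is gene activation (`k_on`) plus translation (`k_tl`): ε =
0.754 means 75% of the noise control vector survives the mean constraint.
The direction itself:

```sh
$ stocan design-orthogonal --fixture two_state_promoter --species protein --params k_on,k_tl
{
  ...
  "direction": [0.7432941462471663, -0.6689647316224498],
  "efficiency": 0.7291045398809776,
  "strength": 0.7797694819247962,
  "impossible": false
}
```

i.e. raise activation and lower translation in the ratio 0.74 : −0.67 —
noise falls at 0.78 %/% of perturbation, the mean stays put to first order.
(Without the 5% tolerance the pair efficiency is 0.729.)

Contrast the birth-death process `∅ → X → ∅`, whose stationary law is
Poisson:

```sh
$ stocan ccs --fixture birth_death
variable,species,parameter,lag,scaled,unscaled
mean,X,k_s,,1.0,2.5
noise,X,k_s,,-1.0,-0.1
mean,X,k_d,,-1.0,-12.5
noise,X,k_d,,1.0,0.5
```

Mean CCs (+1, −1) and noise CCs (−1, +1) are exactly anti-parallel, so
`design-orthogonal` reports efficiency 0 with an `impossible` flag: you
cannot change this species' noise without moving its mean.

## Layout

| module | contents |
| --- | --- |
| `stocan.network` | species/parameters/reactions, rate-law grammar, `N = L·N_R` decomposition |
| `stocan.schema` | native text model format, SBML L3 import |
| `stocan.lna` | steady state, Lyapunov covariance, noise levels, autocorrelations |
| `stocan.sensitivity` | analytic CCs + finite-difference oracle |
| `stocan.design` | control vectors, orthogonal/generalized/tolerance designs, ranking, iteration, oscillation scores |
| `stocan.simulate` | Gillespie SSA, Euler–Maruyama, stationary estimators |
| `stocan.fixtures` | birth-death, two-state promoter, metabolic chains, feedback oscillator |
| `stocan.cli` | `stocan` command-line tool |

See `docs/methods.md` for modeling assumptions, defaults, and numerical
choices.
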