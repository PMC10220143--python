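# Methods

## Model

The state is the vector of haplotype frequencies of an `ℓ`-locus system,
a point on the simplex Δ_{d−1}, d = ∏ K_j, with haplotypes stacked
row-major/lexicographically in the locus indices (two loci: haplotype
(i, j) ↦ flat index (i−1)L + j). The diffusion has Wright–Fisher
covariance `V_ij(x) = x_i(δ_ij − x_j)` and drift `μ = c + a` where `a`
carries the parameters under estimation and vanishes at the reference
parameter, and `c` is treated as known. Components:

- recombination (two loci): `a_ij = ρ(x_{i·}x_{·j} − x_ij) = −ρ D_ij`,
  with `D` the per-haplotype linkage disequilibrium. **Timescale:** ρ is
  the crossover rate on the diffusion timescale *without* the conventional
  factor 1/2; mutation and selection keep their 1/2 factors. This is fixed
  package-wide and stated in the `params` module docstring.
- recombination (ℓ loci): `a_i = Σ_j ρ_j (x_{i≤j} x_{i>j} − x_i)` with
  prefix/suffix marginals over the cut after locus j.
- mutation: `c_ij = θ_A/2 Σ_k x_kj(P^A_ki − δ_ik) + θ_B/2 Σ_l x_il(P^B_lj − δ_jl)`
  with row-stochastic transition matrices (validated to 1e−9).
- selection: diploid epistatic tensor `s_{ij,kl}` (stored dense; symmetry
  is not required of the general model and is not enforced), the additive
  special case `s_{ij,kl} = s^A_{ik} + s^B_{jl}`, or genic selection at
  one locus. All drift components sum to zero over haplotypes — the
  algebraic condition for staying on the simplex — and this is enforced
  by tests to 1e−12 on random states.

Mutation is modelled for two loci only; for ℓ > 2 the package simulates
and estimates pure recombination (a model restriction, rejected loudly if
θ > 0 is requested with ℓ > 2).

## Likelihood functionals and estimators

For drift linear in the parameters, `a_i = Σ_k Z_ik(x) φ_k`, the path
log-likelihood against the φ = 0 reference is
`log L_T(φ) = φ'Y − ½ φ'I_T φ` with
`Y_k = ∫ Σ_i Z_ik/X_i dX̃_i` and `I_kl = ∫ Σ_i Z_ik Z_il / X_i dt`,
where `X̃` is the path compensated by `∫ c`. The MLE solves `I_T φ̂ = Y`.
Specializations implemented: the two-locus recombination estimator, the
genic selection estimator
`ŝ = 2(X̃_{k·}(T) − X_{k·}(0)) / ∫ X_{k·}(1−X_{k·}) dt`, the joint
(ρ, s) fit (whose information matrix is exactly diagonal, verified
pointwise), and the ℓ-locus joint and shared-rate estimators.

Numerical conventions:

- All stochastic integrals are left-endpoint (Itô-consistent) Riemann
  sums on the simulation grid, matching the Euler–Maruyama
  discretization. With this pairing the martingale error identity
  `ρ̂ − ρ = −N_T/I_T` holds *exactly* in the discrete scheme (tested to
  1e−10), because the per-step drift contribution to Y is exactly ρ times
  the per-step information increment.
- Integrals stop at the last grid point at which every coordinate is
  strictly positive — the discrete proxy for the limit t ↑ S in the
  corrected estimator; the clipped step itself is excluded since 1/X_ij
  is undefined at the clipped point.
- The corrected estimator is rectified onto [0, ∞) in all conventions;
  discretization noise can push the pre-explosion limit slightly negative
  although the continuous-time limit is the (non-negative) true rate.
- An optional frequency floor ε restricts the integrands to
  {ε ≤ X_ij ≤ 1−ε} per haplotype (default off; the continuous-time model
  has no floor).
- Both printed forms of the information (`Σ(X_ij − X_{i·}X_{·j})²/X_ij`
  and `Σ X_{i·}²X_{·j}²/X_ij − T`) are implemented and agree to rounding
  on the same grid; the direct form is the default because it is
  manifestly non-negative.

## Exploded paths: two valuation conventions

If a haplotype frequency hits zero before T the observed information
diverges and the corrected estimator equals the true rate almost surely.
Two conventions for valuing such replicates are implemented and always
recorded in output:

- `limit_at_S` (estimator default): the estimator computed on the
  pre-explosion segment, rectified. This is the honest out-of-sample
  value — it uses only data.
- `truth_assigned` (experiments default): the replicate is scored as
  exactly the true rate, which is what the exactness result licenses in a
  simulation study where the truth is known.

The replicate-study summary's "frequency of zero error" column is defined
as the *explosion frequency*. Empirically this is what the reference
summaries report: at (θ = 5, ρ = 0) the printed value 0.11 matches the
explosion count, while literal zero-error counting would also include
raw-negative estimates rectified to 0 (≈ 0.4 of replicates).

## Simulator

Euler–Maruyama with the bounded symmetric square root
`σ_ij = √x_i(δ_ij − √(x_i x_j))`, `σσ' = V`, driven by d Brownian
coordinates. The Cholesky factor is deliberately avoided: it diverges at
the simplex boundary, exactly where this problem is most interesting. If
a proposed coordinate is ≤ 0 it is clipped to zero, the state is
renormalized to the simplex, the step index and time are recorded as the
explosion, and simulation continues to T (useful for diagnostics);
estimators consume only the pre-explosion segment. The clipping threshold
is exactly 0 by default (an ε floor is exposed). Replicates draw from
`SeedSequence` substreams so any replicate is independently reproducible;
trajectories can store their Brownian increments, and replaying stored
increments regenerates the path bit-for-bit.

Storage thinning (`thin_stride`) affects stored output only. Likelihood
functionals refuse thinned trajectories; large replicate batches instead
use a numba streaming kernel that accumulates Y and I_T at full step
resolution without storing paths. The kernel is validated against the
reference simulator + functionals by injecting a shared noise array
(agreement to 1e−13, interior and exploding paths alike).

## Hypothesis test

Λ = ρ̂²_MLE I_T for finite information; on explosion Λ = +∞ if the
estimate is positive, 0 if it is zero. Because ρ₀ = 0 sits on the
parameter-space boundary the null is the equal χ²₀/χ²₁ mixture, so the
level-α threshold is the (1 − 2α) quantile of χ²₁ (2.7055 at α = 5%).
The null in the explosion regime is unknown; the mixture threshold is
retained as a conservative choice (an exploding null replicate has a
zero estimate and never rejects under truth scoring).

## Deterministic oracles

With θ = 0 the noise-free dynamics relax to linkage equilibrium as
`x_ij(t) = x_ij(0)e^{−ρt} + x_{i·}(0)x_{·j}(0)(1 − e^{−ρt})`, marginals
conserved, and the information has the closed form
`I_T = ρ^{-1} Σ x_{i·}(0)x_{·j}(0) log(x_ij(T)/x_ij(0))` with a finite
T → ∞ limit. The path estimator applied to this gridded trajectory
returns ρ with O(dt) error (first-order convergence verified by step
halving). With mutation present, or for ℓ > 2, the deterministic system
is integrated numerically (`solve_ivp`, RK45 at tight tolerance) and only
the finite-information-limit property is asserted, since no closed form
is implemented for those regimes.

## Robustness

The condition for a confounder `c` to leave an estimator unchanged is
`Σ_i Z_ik c_i / x_i = 0` for every parameter k. Classification is
numeric: the condition is evaluated at ≥100 Dirichlet(1) points with a
fixed seed and declared zero when |R_k| ≤ 1e−10 times the sum of absolute
terms; a problem is robust only if every sampled point agrees. The
catalog reproduces: robust — recombination vs non-epistatic selection,
selection vs recombination, mutation at one locus vs selection at the
other, selection at one locus vs mutation at the other; not robust —
recombination vs mutation, mutation vs mutation, mutation vs
recombination, mutation vs same-locus selection, selection vs same-locus
mutation (and the locus-swapped variants). The selection-adjusted
estimator subtracts `(1/I_T)∫ Σ(X_{i·}X_{·j} − X_ij) Σ (s_{ij,kl}/2)X_kl dt`;
for additive selection the integrand cancels identically, so the plain
estimator is unbiased by ignored non-epistatic selection.

## Replicate study: what is emulated, at what sizes

The synthetic-data generator *is* the study design: diallelic two loci,
symmetric parent-independent mutation (all transition entries 1/2),
x(0) = (2/5, 1/5, 1/5, 1/5), dt = 1e−6, T = 1, θ ∈ {1, 5},
ρ ∈ {0, 0.1, 1, 2.5, 5, 10, 25}, 100 replicates per cell, exploded
replicates scored by `truth_assigned`, percentiles by the inclusive
linear-interpolation convention. The acceptance script runs this full
grid at dt = 1e−6; the test suite replicates four representative cells at
dt = 1e−5 with 100 replicates, a step size at which the cell summaries
remain within Monte-Carlo error of the full-resolution values while
keeping the default test run fast. Explosion frequencies in the
high-mutation regime are partly discretization artifacts (the boundary is
inaccessible in continuous time at θ = 5), are dt-sensitive, and are
reported alongside each summary so the sensitivity is visible.

What the generator does *not* emulate: finite population size (true
frequencies multiples of 1/N — the diffusion's boundary behaviour
overweights rare haplotypes relative to a discrete population), sampling
noise (the whole path is observed exactly), and temporally sparse
observation. Passing tests therefore certify the estimator under its own
idealised model, not performance on real time-series data.

## Known limitations

- Exact (rejection-sampler) simulation is not available for these
  non-reversible diffusions; all paths are Euler–Maruyama, so explosion
  times carry O(dt) bias.
- The ε-restricted estimator is exposed but unstudied here; the
  LD-normalization summaries suggested by the score/information
  integrands are out of scope.
- No asymptotic (LAN) theory: standard errors for ρ̂ should come from the
  observed information or replicate spread, not normal asymptotics.
- `estimate` CLI batch aggregation is by appending rows to a shared CSV.
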