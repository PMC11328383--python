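# Methods

## The model

`ssblup` implements multi-trait single-step genomic prediction in its
SNPBLUP form, with optional trait-specific marker weights.  The linear
mixed model for T traits is

    y = Xb + Wu + e,      u ~ N(0, G0 ⊗ H),    e ~ N(0, R),

where `u` stacks additive genetic effects of non-genotyped and
genotyped animals, `G0` is the T×T genetic covariance and `H` the
combined pedigree–genomic relationship matrix.  Three equivalent
formulations of the mixed model equations (MME) are provided:

1. **Classical single-step GBLUP** (breeding values only).  The random
   effect precision is `G0⁻¹ ⊗ H⁻¹` with
   `H⁻¹ = A⁻¹ + [0 0; 0 G_C⁻¹ − A_gg⁻¹]`, `A` the pedigree numerator
   relationship matrix and `G_C = Z_c B Z_c' + C` the regularized
   genomic relationship matrix.  Kept dense, as a desk-scale oracle.
2. **Single-step SNPBLUP with common marker weights.**  Marker effects
   `g` enter the equations explicitly; the marker block is
   `G0⁻¹ ⊗ K` with `K = Z_c'C⁻¹Z_c + B⁻¹`, the animal block uses
   `H_C⁻¹ = A⁻¹ + [0 0; 0 C⁻¹ − A_gg⁻¹]`, and the coupling is
   `−G0⁻¹ ⊗ K_C` with `K_C = [0; C⁻¹Z_c]`.  No genomic matrix is ever
   formed or inverted; the coefficient matrix is applied matrix-free.
3. **Trait-specific marker weights.**  Only the marker–marker block
   changes, to `G0⁻¹ ⊗ Z_c'C⁻¹Z_c + V_g⁻¹`, where `V_g` is block
   diagonal with one T×T covariance per marker,
   `V_{g,k} = D_(k)^{1/2} G0 D_(k)^{1/2} · scale` under the
   correlation-one cross-trait rule `D_ij = (D_ii D_jj)^{1/2}`.
   Storage is m·T², never (mT)².

Centering uses base-population allele frequencies (`Z_c = M − 2p`), the
scaling constant is `s = 2Σ p_k(1−p_k)`, and the regularization is
either `C_e = eI` (default e = 0.01) or the residual-polygenic form
`C_w = w A_gg` (default w = 0.05, the value used in all study runs).
Weight columns are standardized to mean 1; zero weights are floored at
1e−6 before standardization because every `V_{g,k}` must be positive
definite.

A note on the G_u Woodbury identity used as an oracle: for the dense
trait-specific covariance
`G_u = (I⊗Z_c)V_g(I⊗Z_c') + G0⊗C`, the correct inner matrix is
`(G0⁻¹ ⊗ Z_c'C⁻¹Z_c) + V_g⁻¹` — consistent with the marker block of the
trait-specific MME — and the implementation verifies
`G_u⁻¹G_u = I` to ~1e−14 on random instances.

## Solver

The MME are solved with classical Hestenes–Stiefel preconditioned
conjugate gradients.  The preconditioner is block diagonal with one
T×T block per effect level: exact diagonal blocks of the coefficient
matrix for fixed-effect and animal levels, and for marker k

    G0⁻¹ c_k + V_{g,k}⁻¹,    c_k = (1/w) Z_{c,k}' D_A Z_{c,k},

with `D_A = diag(A_gg⁻¹)` (for `C_e`, `c_k = Z_{c,k}'Z_{c,k}/e`, which
is exact).  Convergence is declared when the relative residual
`C_r = ‖C s − r‖/‖r‖` drops below 1e−7 (default); `C_r` is tracked from
the recursively updated residual with a true-residual recomputation
every 100 iterations to guard against drift.  `maxiter` defaults to
50,000 and exceeding it raises with the final `C_r`.  On the simulated
study the block preconditioner roughly halves the iteration count
relative to unpreconditioned CG, and weighted systems take more
iterations than unweighted ones, increasingly so the more the weights
deviate from 1.

## Pedigree algebra

Inbreeding is computed by the dense tabular method up to 5,000 animals
and by the Meuwissen–Luo recursion above that (both agree exactly on
overlapping sizes).  `A⁻¹` is assembled sparse by Henderson's rules
with inbreeding.  `A_gg` is built by a tabular fill restricted to the
ancestor closure of the genotyped subset, so the full A is never
materialized.  Unknown parents are base-population draws (variance 1,
no metafounders or genetic groups).

## Two-step weight estimation

1. **Animal model.**  Multi-trait pedigree BLUP with a general mean per
   trait; prediction error variances come from the direct inverse of
   the MME coefficient matrix, giving exact reliabilities
   `r²_it = 1 − PEV_it/((1+F_i) G0_tt)`.  This replaces production-scale
   reliability approximations and is valid at the pedigree sizes this
   package runs (the dense inverse is the cost ceiling of the
   pipeline).
2. **Deregression.**  For each animal with own or progeny phenotypes,
   the own-information and parent-average-information contents
   `(l_i, l_PA)` are recovered in closed form from `(r²_i, r²_PA)` by
   inverting the reliabilities of the two-equation (parent-average,
   animal) BLUP system with λ-scaled pedigree precision
   `λ[[4,−2],[−2,2]]`, `λ = (1−h²)/h²` and `r²_PA = (r²_s + r²_d)/4`.
   Then `DRP = (−2λ·PA + (l_i+2λ)·EBV)/l_i`,
   `r²_DRP = l_i/(l_i+λ)`, and the record weight is
   `(1−h²)/((c + (1−r²_DRP)/r²_DRP)h²)` with c = 0.5.  Animals whose
   recovered own information is non-positive are dropped with a
   warning.
3. **BayesA.**  One single-trait Gibbs sampler per trait on the
   deregressed proofs of genotyped animals: marker effects conditionally
   normal; marker variances scaled-inverse-χ²(ν+1) updates with prior
   ν = 4.2 and prior scale chosen so the prior mean marker variance is
   `G0_tt/s`; residual variance scaled-inverse-χ² with a weakly
   informative prior (ν_e = 4, scale var(y)/2) and record weights as
   inverse residual-variance multipliers.  Chains are deterministic
   given the seed.  Defaults are 20,000 iterations with 4,000 burn-in;
   the reduced-scale study runs use 1,500/300, which is sufficient for
   posterior-mean weights at the panel sizes involved (weight rankings
   are stable across seeds in the recovery tests).  Posterior mean
   variances scaled to mean 1 are the marker weights.

The hot Gibbs loop is compiled with numba; a pure-NumPy implementation
of the identical algorithm is kept as a fallback and for line-level
inspection (the two use different RNG streams, so chains match within a
path, not across paths).

## Simulated breeding study

One replicate emulates the two-trait selection program the evaluation
targets:

* **Founders.**  msprime coalescent, one population, piecewise-constant
  Ne: 280 up to 1,000 generations ago, 10,000 before — a neutral
  approximation of a domesticated-cattle history ending at Ne = 280.
  30 chromosomes of 1 Morgan (1e8 bp at 1e−8 recombination and mutation
  per bp), 2,800 male and 2,800 female founders.
* **Architecture.**  30 QTL per chromosome sampled from segregating
  sites; per-trait effect magnitudes gamma(0.4, 1.0) with signs and
  cross-trait dependence from a Gaussian copula whose correlation is
  calibrated (Brent root-finding on the realized founder genetic
  correlation) to −0.3; effects rescaled so founder genetic variances
  equal h² = 0.3 (production) and 0.1 (adaptation) on phenotypic
  variance 1; residual correlation 0.  The SNP panel takes 1,800 evenly
  spaced non-QTL segregating sites per chromosome (54,000 total).
* **Breeding.**  The base population mates randomly, one offspring per
  mating; every later generation selects the best 200 males and 2,800
  females from the current breeding population plus the newest
  offspring, ranked by an equally weighted index of within-cohort
  standardized own phenotypes; each of the 2,800 matings (random
  dam–sire pairing, sires reused) produces one offspring; sexes
  alternate deterministically so cohorts are exactly balanced; meiosis
  draws Poisson(map length) crossovers without interference.  Ten
  generations.
* **Evaluation data.**  Phenotypes of all females except the last
  generation; genotypes for sires of phenotyped females plus all
  animals of the last three generations; validation animals are the
  genotyped last generation.  Augmented panels add the largest QTL —
  ranked by `2p(1−p)·mean_t(a_t²/h²_t)`, the across-trait mean share of
  genetic variance — until the added set explains 5% or 20% of it.
  Base allele frequencies are recorded from the founders and reused for
  centering (`method="known"`); an observed-mean estimator is the
  fallback for external data.

**Down-scaling.**  `scale` multiplies every population count, the
panel size and the QTL count, and also shortens the founder coalescent
map per chromosome by the same factor (positions are then stretched
onto the full 1-Morgan meiosis map).  The second part keeps marker
density per unit of founder genetic map — and hence marker–QTL LD —
comparable across scales, and makes the deep-history coalescent cost
proportional to scale.  At scale = 1 both rules are the identity.  The
reduced-scale runs used by the test suite and the acceptance script use
scale = 0.1 (3,360 animals, 5,400 SNPs, 90 QTL, 280 validation animals,
three replicates) and scale = 0.01–0.02 for smoke tests.

**What the generator does not emulate.**  Real cattle demography beyond
a two-epoch Ne history; mutation after the founder stage; crossover
interference; age-structured overlapping generations; systematic
environmental effects (the only fixed effect is a general mean, so the
evaluation model is exactly the generating model up to the marker
panel).  Passing study-level tests therefore demonstrates the internal
consistency and the direction of the weighting effect under the stated
design, not performance on real data, where gains are expected to be
smaller.

## Reduced-scale behavior and limitations

At 1/10 scale, averaged over three replicates, trait-specific weighting
raises validation accuracy for both traits (production r ≈ 0.70 → 0.76;
adaptation r ≈ 0.50 → 0.51) and lowers the production regression
coefficient (b ≈ 0.92 → 0.90), the same directions as the full-scale
design this study follows.  Two full-scale phenomena do not survive the
down-scaling and are deliberately not asserted: (i) the unweighted
model is not unbiased (b ≈ 0.9–1.2 rather than ≈ 1.0) because the
validation cohort is 10× smaller and drift is stronger; (ii) the
adaptation weights are nearly flat (per-replicate SD ≈ 0.13, against
6.8/2.4 for production/adaptation at full scale), so the weighted and
unweighted adaptation models nearly coincide and no b direction is
resolvable for that trait.  Production weights always vary more than
adaptation weights, which the tests do assert.

## Numerical choices

* Positive-definiteness of each `V_{g,k}` is checked via the smallest
  eigenvalue (> 1e−12·trace); user-supplied cross-trait weights that
  break it are rejected rather than repaired.
* Monomorphic markers are kept with frequencies clipped to
  [1e−6, 1−1e−6] so panel sizes stay exactly as configured.
* Residual covariance R0 may be dense; records with missing traits
  contribute through the inverse of R0 restricted to the observed
  subset (cached per missingness pattern).
* Equation layout is level-major — T consecutive equations per effect
  level, animals ordered non-genotyped before genotyped — matching the
  block preconditioner's structure.
* All randomness flows from explicit integer seeds; replicate r uses
  base seed + r, and the BayesA seed is offset per trait so chains are
  independent.
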