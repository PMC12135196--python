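# Methods

## The problem

Under genomic selection, heritabilities and genetic correlations can change
noticeably within a few generations (Bulmer-effect variance erosion, drifting
trait definitions).  Classical estimators (REML, Gibbs sampling) scale poorly
with the number of genotyped animals, so parameters in routine evaluations are
often years out of date.  `predslice` implements a closed-form alternative:
every quantity is derived from *predictivity* — the correlation between
validation animals' fixed-effect-adjusted phenotypes and their GEBVs computed
without those phenotypes — which is available whenever a genetic evaluation
can be run at all.  The cost of parameter estimation is then the cost of the
evaluation itself.

## Estimators

Model: `y = Xb + u + e`, `u ~ N(0, G σu²)`, `e ~ N(0, I σe²)`,
`h² = σu²/(σu² + σe²)`.  Writing `c = Corr(y − Xb̂, û)` on a validation set of
size `n`, with a reference of `N` genotyped-and-phenotyped animals and `Me`
independent chromosome segments:

* accuracy from predictivity: `acc = c / h`;
* expected accuracy: `acc = sqrt(N h² / (N h² + Me))`;
* equating the two and solving for `h²`:
  `ĥ² = (c² + sqrt(c⁴ + 4 c² Me / N)) / 2`;
* genetic correlation from the cross-trait predictivity
  (phenotype of trait *i*, GEBV of trait *j*):
  `r̂_g = Corr(y_i − X b̂_i, û_j) / (h_i · acc_j)`;
* SE bounds, treating `h` and `acc` as constants: `SE(acc) ≤ 1/(h_i √n)`,
  `SE(r̂_g) ≤ 1/(h_i · acc_j · √n)`; and the linearized
  `SE(ĥ²) ≈ (1/(2√n)) [c + (2c² + 4Me/N)/sqrt(c² + 4Me/N)]`, which tends to
  `1.5 c/√n` for `N ≫ Me`.

Notes the implementation commits to:

* Estimates outside their natural range ([0,1] for `h²`/`acc`, [−1,1] for
  `r_g`) are clamped; the raw value is kept on the estimate object and a
  warning is emitted (an accuracy above 1 usually means `Me` or `N` is off).
* `SE(ĥ²)` is implemented exactly as the closed form above.  That form is the
  linearization the field uses, but it is *not* the exact derivative of the
  estimator: `d ĥ²/dc = (1/2)[2c + (2c²+4Me/N)/sqrt(c²+4Me/N)]`, whose
  large-`N` limit is `2c/√n` rather than `1.5c/√n`.  The test suite pins the
  implemented form and documents the constant `c/(2√n)` gap to the exact
  slope.  The SE is undefined at `c = 0` and reported as absent there.
* The two orderings of a genetic correlation (`(i,j)` vs `(j,i)`) are equal
  asymptotically but not in finite samples; both are always computed and
  reported.  For a drifting composite trait, predicting the *fast-changing*
  phenotype from the *stable* trait's GEBV has the smaller lag, because the
  GEBV of a composite trait is trained on past generations.
* The minimum-reference rule `N > Me/(3h²)` is the printed closed form; at
  its boundary the expected accuracy is exactly 0.5.

## GBLUP machinery

* GRM: VanRaden method 1, `G = ZZ′ / (2 Σ p(1−p))`, allele frequencies from
  the combined reference+validation set, blended `(1−α)G + αI` with
  `α = 0.05` so the matrix is positive definite.  Monomorphic-only marker
  sets are rejected.
* Solver: the mixed-model equations are solved through the equivalent
  reference-block form `V = σu² G_rr + σe² I`, `û = σu² G[:,ref] V⁻¹ (y−Xb̂)`
  with a GLS fixed-effect estimate, by dense Cholesky.  Only the variance
  ratio `λ = (1−h²)/h²` matters, so phenotypes need no variance
  standardization.  Equality with an explicit MME inversion is enforced by a
  property test on random instances.
* Fixed effects: an overall mean, or one categorical factor in cell-means
  coding.  Validation individuals enter `G` but never the right-hand side.
* Traits are evaluated univariately with zero assumed genetic covariance;
  missing genotypes are not supported (pre-impute or drop).

## Independent chromosome segments

`me_from_ne_l` returns `4 Ne L` (L in Morgans).  `me_from_grm_eigenvalues`
counts the leading eigenvalues explaining 98% (configurable) of the variation
of the *unblended* G — blending flattens the spectrum tail and would distort
the count; negative numerical eigenvalues are truncated at zero; matrices
beyond 5,000 individuals are randomly subsampled.  The spectral count is only
meaningful when the matrix holds clearly more individuals than the expected
`Me`; otherwise it saturates near `0.98 n`.

## Time-slice procedure

For each sliding window (default: two consecutive reference generations, the
next generation as validation):

1. GRM over the window's individuals; univariate GBLUP per trait with the
   current heritabilities, reference phenotypes only.
2. Predictivities of validation adjusted phenotypes against GEBVs, within and
   across traits.
3. `h²` per trait from its within-trait predictivity, with `N` = reference
   animals having both genotype and phenotype *for that trait*.
4. Repeat 1–3 with the updated heritabilities until the largest per-trait
   change is below `tol = 0.01` or `max_iter = 10` is reached (with accurate
   starting values one refinement pass converges; wrong-by-2x starting values
   typically need one or two more).  Non-convergence is reported, never
   silently accepted.
5. Accuracies `c/h` at the final `h²`, both orders of each `r_g`, and the
   closed-form SEs evaluated at the final values.

Per-window failures (e.g. degenerate predictivities) are flagged rows, not
fatal errors.  Windows are independent; trends come from running all of them.

## The simulator

`run_generations` emulates the validation study:

* Genome (desk-scale default): 10 chromosomes × 100 cM, 500 markers + 30 QTN
  per chromosome.  Meiosis is Haldane: Poisson crossover counts in map
  length, uniform positions, no interference, no mutation.
* Traits: QTN effects are gamma(0.4)-magnitude with random sign (shape chosen
  for a leptokurtic, few-large-effects architecture), drawn independently for
  traits 1 and 2 and rescaled so generation-0 `var(u) = 1`; breeding values
  are *always* computed from QTN genotypes and expressed as deviations from
  the generation-0 mean.  Residual variances 1.5 / 9 / 9 give founder
  heritabilities 0.40 (production), 0.10 (scaffold and fitness).
* The fitness trait is the engineered composite
  `u3 = α_j [u2 − β u1 (u1 − ū₁₀)]` with `α_j` restoring unit variance within
  each generation and `ū₁₀` frozen at the generation-0 mean; as selection
  shifts `u1`, `corr(u1, u3)` drifts downward.  `calibrate_beta` bisects `β`
  on pilot simulations until the mean decline hits a target (−0.1 per
  generation); the shipped default `β = 0.115` is the output of that calibration at
  the default scale.
* Selection: top 13 sires and 500 dams (desk scale; the dam-selected fraction
  and `Ne = 4·Nm·Nf/(Nm+Nf) ≈ 50` match an industrial nucleus) on trait-1
  GEBV from a within-generation GBLUP run with the *initial* `h² = 0.4` every
  generation; each dam leaves an equal number of offspring, sires are drawn
  uniformly per mating, offspring sexes are Bernoulli(1/2).
* Founders: haplotypes are drawn per locus at uniform allele frequencies and
  the population is then random-mated at a bottleneck size of 200 for 10
  generations before expanding to full size.  This recent-small-`Ne` history
  gives the founder genome the drift–recombination LD structure of a
  livestock nucleus, so that the population's effective segment number is
  consistent with the `Me = 4 Ne L` premise the estimation procedure relies
  on; with unrelated founders the early windows would systematically violate
  that premise.

What the generator does *not* emulate: genotyping errors, missing data,
pedigree errors, non-additive gene action, overlapping generations, selective
genotyping, and deep coalescent founder history.  Passing tests therefore
show parameter recovery under the model's own assumptions, not robustness to
real-data pathologies.

## Problem sizes and expected precision

The replicated study in the tests and acceptance script runs 2,000 offspring
per generation over 7 generations (≈14,000 individuals, 5,000 markers) with 4
(tests) or 12 (acceptance script) replicates — a deliberate scale-down of the
40,000-per-generation study it mirrors.  Two consequences worth keeping in
mind when reading its numbers:

* With `n = 2,000` validation animals and cross-trait predictivities around
  ±0.1, a single window's genetic-correlation estimate carries a sampling SE
  of roughly 0.1 (vs ~0.03 at full scale); only replicate means are
  informative at this scale, and the stricter (fitness-phenotype) ordering's
  0.05 recovery bound sits at the edge of what the replicate budget resolves.
* With `N = 4,000` reference animals against `Me ≈ 2,000`, `N h²` is only ~2–4
  times `Me`, so the heritability estimate is sensitive to the assumed `Me`
  in a way the full-scale study (ratio ≈ 13) is not; the earliest window,
  whose reference generations retain the most founder structure, shows the
  largest residual deviation.

## Numerical conventions

Variances and standard deviations use `ddof = 1` throughout (trait scaling,
composite `α_j`, realized parameters).  All randomness flows from one seed
through `numpy` `SeedSequence` spawning; simulations are bit-reproducible for
a fixed seed and package version.  Cholesky factorizations operate on copies;
the GRM is never overwritten.  Windows with constant GEBVs (infinite
shrinkage) raise degenerate-input errors and are flagged.
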