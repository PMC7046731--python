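# Methods

`knockloc` localizes trait-associated genetic variants by testing
*conditional* association hypotheses for contiguous groups of variants at
several nested resolutions, with false discovery rate (FDR) control at each
resolution.  This note records the models, the algorithms, the tunable
parameters, and the design choices that were genuinely open.

## Hypotheses

For a partition `G = (G_1, ..., G_L)` of the `p` variants into contiguous
blocks, group `g` is **null** when the trait `Y` is independent of the
variants in `G_g` given all variants outside `G_g`.  Rejections therefore
point at genomic segments carrying signal that is *distinct* from their
surroundings, not merely correlated with it through linkage disequilibrium
(LD).  A ladder of nested partitions — coarse LD blocks down to single
variants — trades localization against power: narrow groups are harder to
separate from their neighbors.  Partitions are fixed from genotype data
alone, before any phenotype is read; the pipeline enforces this ordering.

## Genotype model: haplotype-cluster HMM

Each haplotype is a mosaic of `K` latent ancestral clusters.  At site `j`
the latent state persists with probability `1 - r[j]` or jumps (a
recombination event) to a cluster drawn from local weights `alpha[j]`
(`r[0] = 1` by convention); given cluster `k`, the alternate allele appears
with frequency `theta[j, k]`.  Parameters are fitted by EM (Baum–Welch) on
phased haplotypes; recursions are scaled per site, so likelihoods are
stable for arbitrarily long chromosomes.

* **K** (default 5 in the desk-scale pipeline, configurable): enough to
  capture the block-like LD of the synthetic data; real cohorts typically
  need several dozen clusters.
* **EM initialization**: `theta ~ Uniform(0.1, 0.9)`, uniform `alpha`,
  constant `r = 0.1`; default 3 restarts (the pipeline uses 1), keeping the
  restart with the best final log-likelihood.  EM is ascent, so the
  per-iteration log-likelihood trace is non-decreasing; tests assert this
  with slack 1e-6.
* **Subsampled fitting**: the pipeline fits the model on a random subset of
  800 haplotypes by default (`PipelineConfig.em_subsample`); with p=600 and
  K=5 this estimates the ~6,600 free parameters accurately at a fraction of
  the cost, and knockoffs are still generated for every haplotype.
* Missing genotypes are mean-imputed per variant before fitting and before
  regression — the simplest deterministic choice.

Unphased input is handled by sampling a phasing from the fitted model's
posterior and proceeding as if phased; with genuinely phased data this
implicit re-phasing is skipped, which is both faster and statistically
cleaner.

## Group knockoffs

Knockoff genotypes are synthetic negative controls satisfying, for every
group `G`: the joint law of `(X, X~)` is invariant when the coordinates in
`G` are swapped between the two copies, and `X~` is constructed without any
access to `Y` (the knockoff module has no phenotype input anywhere in its
API).  Construction per haplotype:

1. sample a latent path `z` from the exact posterior `P(Z | h)`
   (backward-sampling from scaled forward quantities);
2. sample a knockoff path `z~` group by group, left to right along the
   genome, each group's states drawn **jointly** from the knockoff
   conditional given `z` and the previously sampled knockoff groups
   (sequential conditional independent pairs).  The group-boundary factor
   involves the previous group's normalizing function, which is propagated
   by a forward dynamic program; everything costs `O(p K^2)` per haplotype,
   and the production implementation vectorizes all haplotypes at once in
   `O(p K)` per haplotype by exploiting the jump–persist structure of the
   transitions;
3. re-emit alleles at the knockoff states from `theta`.

Knockoff genotypes are the within-individual sums of the two knockoff
haplotypes.  Group processing order is genomic left-to-right: the
construction is valid for any order, and this keeps the dynamic program
banded.  A separate exact-enumeration oracle (`exact_joint_pmf_small`)
computes the full joint pmf `P(h, h~)` from the sampler's own conditionals
on models with `p <= 4`, `K <= 3`; the test suite verifies group-swap
invariance of that table to 1e-10 for every contiguous partition of 3 and 4
sites, and the vectorized sampler is checked against the enumerated
conditionals empirically.

## LD partitions

Similarity is the squared Pearson correlation `r^2` of allele counts
(computed on haplotypes when available), banded at a window of 1000
variants.  Clustering is adjacency-constrained agglomerative with
**complete linkage** on `1 - r^2`: only genomically adjacent clusters may
merge, ties go to the leftmost pair, and complete linkage both bounds the
within-group dissimilarity (groups are sets of variants too similar to
disentangle) and guarantees non-decreasing merge heights under the
constraint.  Cutting the tree at descending heights yields nested
partitions by construction.  Cut heights are chosen to hit target mean
group widths; the desk-scale default ladder targets 25 kb, 10 kb, and 2 kb
(single variant at the default 2-kb spacing).  With a nominal level
`q = 0.1` the filter cannot report fewer than `1/q = 10` discoveries, so a
desk-scale study with ~6 causal loci needs each resolution to contain
comfortably more than 10 discoverable groups; the 25-kb coarse level is the
coarsest that satisfies this.

## Importance statistics

A lasso (linear for continuous traits, logistic for binary) is fitted to
the augmented design `[Z, X, X~]` with `X` and `X~` standardized.
Covariates `Z` (plus an intercept) are unpenalized: the linear path
profiles them out exactly (Frisch–Waugh partialling); the logistic path
rescales them by 1e4, making their effective penalty negligible.  Within
each (original, knockoff) column pair the order is randomized with a
recorded seed so solver tie-breaking cannot favor originals.  The penalty
is chosen by cross-validated deviance on a log-spaced grid down to
`1e-4 * lambda_max`; the package default is 50 grid points and 5 folds,
which on problems of this size selects essentially the same penalty as a
denser grid at a fraction of the cost.  Group importances are
`T_g = sum_{j in G_g} |beta_j|` over original columns and `T~_g` over
knockoff columns (covariate coefficients are ignored), combined
antisymmetrically as `W_g = T_g - T~_g`.  Exchangeability makes null `W_g`
symmetric around zero — the package verifies the flip-sign property (column
swapping a group negates exactly its `W`) deterministically.

## Knockoff filter, local FDR, simplified count

The filter picks `tau = min{ t : (1 + #{W <= -t}) / max(1, #{W >= t}) <= q }`
and reports groups with `W >= tau` (ties included).  The `+1` offset gives
provable FDR control; `offset=0` is exposed with a warning that the
guarantee is lost.  The offset implies the `1/q` power floor discussed
above.  Filtering is independent per resolution — the guarantee is per
resolution, with no cross-resolution multiplicity adjustment.

Local FDR estimates (reported when at least 200 groups are available) use
the null sign-symmetry: a Gaussian-kernel density of the negative
statistics reflected about zero estimates the null component, a symmetrized
kernel density of all statistics the mixture; their ratio, scaled by the
estimated null mass `min(1, 2 * #neg / L)`, is clipped to `[0, 1]` and made
non-increasing in `W` by isotonic regression.

Across resolutions, the *simplified count* keeps only the most specific
supported finding per locus: a discovery is supported if the immediately
coarser resolution selected a group containing it (coarsest level is always
supported); unsupported finer discoveries are flagged "floating" and
excluded from the summary, and a supported discovery is masked by any
supported finer discovery inside it.  Whether support should be allowed to
skip a resolution level is genuinely open; the rule here checks only the
immediately coarser level.

## Synthetic data

The generator emulates the study conditions used throughout: a random
haplotype-cluster HMM (`p = 600` variants on a 2-kb grid, `K = 5`, jump
rates ≈ one expected recombination per 50 kb, emission frequencies spread
over (0.05, 0.95)); `n = 2000` diploid individuals; 30 causal variants in
six evenly spaced 0.1-Mb-wide clusters of five; per-cluster relative effect
magnitudes drawn uniformly and affinely rescaled so the smallest-to-largest
ratio is exactly 1/19, with random signs, attached to standardized
genotypes (rarer variants get larger allele-count effects).  Whether the
uniform magnitudes should be drawn per cluster or per variant is left open
by the design; the default is per cluster with a flag to switch.  Gaussian
traits pin the *realized* heritability: the noise is decorrelated from the
genetic value and rescaled so `var(g)/var(y)` equals the target exactly,
which makes replicated FDP/power estimates tighter than enforcing
heritability in expectation.  Binary traits threshold a standardized
Gaussian liability; the desk-scale case–control experiments use a threshold
of 0.52 (≈30% cases) so a cohort of 2000 contains enough cases for a
logistic fit, rather than the extreme imbalance a biobank-scale study can
afford.

What the generator does **not** emulate: population structure and
relatedness, long-range LD, genotyping error, missingness patterns, and
model misspecification of the genotype law (the pipeline re-fits the same
model family it samples from, though with fresh parameters per replicate
and on finite data).  Passing tests therefore demonstrate the method's
internal correctness and its guarantees when the HMM family is adequate;
they do not certify robustness to structured cohorts.

## Problem sizes and numerical choices

Replicated experiments use 25 replicates for FDR checks (the scale at which
the Monte-Carlo standard error of a mean FDP is ~0.01–0.02), 5 replicates
per point for the qualitative power curve and the case–control run.
Numerical details: all forward/backward recursions are scaled per site;
knockoff DP messages are renormalized per site (only ratios matter);
0/0 boundary factors in the knockoff conditional are defined as 0; lasso
solvers use tolerance-bounded coordinate descent (`max_iter=3000`) and
liblinear; EM emission frequencies are clipped to `[1e-12, 1 - 1e-12]`;
zero-variance design columns are kept as all-zeros so their importance is
exactly 0.  Every stage takes an explicit integer seed and is reproducible
byte-for-byte (the CLI writes TSVs with fixed float formatting).

## Known limitations

* The HMM describes homogeneous, unrelated samples; structured cohorts
  need a richer latent model.
* Knockoff generation is randomized: re-running with a new seed gives a
  different, equally valid discovery set.  Re-sampling is exposed behind an
  explicit flag; combining multiple draws into one inference is not
  implemented.
* The local FDR estimator is a smoothing heuristic on top of the
  sign-symmetry and is reported only when groups are numerous.
* The simplified count is a readability device, not a guarantee; floating
  blocks are flagged, not suppressed.
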