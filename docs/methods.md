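# Methods

## Model and hypotheses

For sample *i*, let *y_i* be the trait (continuous or binary), *E_i* the
environmental exposure (continuous or {0,1}), *Z_i* confounder covariates
and *G_i* = (*g_i1*, …, *g_iM*) the minor-allele dosages at the *M*
variants of one SNP set.  The interaction model is the GLM

    f(E[y_i]) = α0 + Z_i a + E_i G_i β + G_i ς + E_i η

with identity link for continuous traits and logit for binary ones.  The
tested hypothesis is β = 0 — no variant in the set has an
exposure-modified effect — with α0, a, ς, η as nuisance parameters.

## Residualization

The score test is performed on residuals.  The trait and each interaction
column *E_i g_im* are adjusted for the design (1, Z, G, E):

* identity link: least-squares residuals for both trait and interaction
  columns (one economy QR of the pruned design, applied to all columns);
* logit link: the trait residual is the response residual y − p̂ from the
  null logistic fit (no interaction terms); interaction columns are still
  adjusted by least squares.  This keeps the permutation scheme — and its
  validity argument — identical across trait kinds.  A linear adjustment
  of a binary trait is also available by passing `link="identity"`.

With an intercept in the design all residuals have mean zero (exactly for
least squares; through the intercept score equation for logistic).
Constant and exactly duplicated adjustment columns are pruned before
fitting (reported, never silent); remaining numerical rank deficiency
raises an error naming the collinear columns (relative tolerance 1e-8 via
pivoted QR).  Interaction columns are deliberately *not* pruned for
collinearity: the statistic below tolerates it, and degenerate columns are
handled there.

## TOW-SE

With centred residuals, per-variant cross-products C_m = Σ_i ỹ_i x̃_im and
variances V_m = Σ_i x̃_im², the optimally weighted score statistic is

    T = Σ_m C_m² / V_m,   attained at weights w_m⁰ = C_m / V_m.

The optimality argument assumes (near-)independent columns, the regime of
rare variants; under strong LD the statistic remains well defined and the
closed form still equals the weighted-combination form (tested), but no
optimality is claimed.  The score normalisation n/Σ ỹ² is permutation
invariant and omitted.  Interaction columns with zero variance (e.g. a
variant carried only by unexposed samples) carry no information: they are
dropped from the sum, their weight reported as undefined, and the drop
surfaced in diagnostics.  Only if every column is degenerate does the test
refuse to run.

## VW-TOW-SE

Variants are split at a MAF threshold (default 0.01; rare means strictly
below).  The stratum statistics T_r and T_c are computed on the shared
permutation stream, standardised by their permutation mean and standard
deviation (sample SD, ddof = 1), and mixed as
T_λ = λZ_r + (1−λ)Z_c over the grid λ ∈ {0, 0.1, …, 1.0} (configurable).
The observed statistic is min_λ p_λ.  The grid realises the continuous
minimum because p_λ is piecewise constant in λ at permutation resolution.

The min-p is corrected within the same permutation set: each permutation
receives its own min_λ of its rank-based p_λ (fraction of permuted values
at least as large, self included), and the corrected p-value is the
add-one rank of the observed min-p among those minima.  With these
conventions two exact properties hold (proved by rank arithmetic and
asserted in tests): the corrected p is never below the raw min-p, and a
degenerate stratum (absent, or zero permutation variance — then its
standardized statistic is set to 0 with a warning) reduces VW-TOW-SE
exactly to the single-stratum TOW-SE p-value.

## Permutation engine

The permutation unit is the residual trait ỹ, reshuffled against the fixed
residual interaction matrix: both are orthogonal to the nuisance design,
so reshuffling breaks exactly the interaction association.  One stream
serves T, T_r, T_c and every λ — required for the paired VW correction and
cheap, since one permuted cross-product matrix yields all per-variant
contributions.  Monte-Carlo p-values use the add-one convention
(1 + #{T_b ≥ T_obs})/(1 + B), bounded below by 1/(B+1).  An exhaustive
mode enumerates all n! orderings (n ≤ 8) and counts plainly, since the
identity ordering is part of the enumeration; comparisons carry a 1e-12
relative slack so mathematically tied statistics recomputed through a
different BLAS path still count as ties.  Reproducibility: one integer
seed governs a run; per-SNP-set streams are derived from (seed,
crc32(set name)), making multi-set runs order independent.

## Data handling

Genotypes load from VCF 4.2 (GT only, diploid biallelic; multiallelic
records are rejected) or a plain TSV of 0/1/2/NA dosages.  Every variant
is oriented to its minor allele at load (flips recorded), so MAF-based
weighting and partitioning are well defined.  Missing genotypes are
mean-imputed per variant by default — the standard choice in rare-variant
testing, preserving allele frequency; imputed dosages are fractional by
construction.  A complete-case policy is available.  Samples are aligned
by identifier in genotype order; samples missing any phenotype field are
dropped with a logged count.  A continuous environment is mean-centred by
default (a binary one is left as coded).

## Simulator

The validation design is a single gene of 8 rare + 2 common variants.
Because the empirical haplotype pool behind the original design is not
redistributable, a synthetic pool stands in: 64 haplotypes, a small group
of common backbones carrying ~72% of the frequency mass and a tail of
low-frequency haplotypes carrying the rest; each variant's minor allele is
placed greedily on a random haplotype subset until its implied frequency
lands in the requested range (rare: [0.001, 0.01); common: [0.05, 0.5]).
Shared haplotypes give the columns weak LD rather than independence.  A
rank check rejects pools whose allele placement would make the genotype
main-effect adjustment structurally collinear.  What this pool does *not*
emulate: real site-frequency spectra, recombination-distance LD decay, or
any specific gene's haplotype structure — so power curves are meaningful
in shape and ordering, not as point estimates for any real locus.  Type I
error conclusions are robust to this choice, since the permutation null
does not depend on the genotype distribution.

Genotypes are two independent haplotype draws per individual.  The trait
follows

    Y = 0.5 Z1 + 0.5 Z2 + α1 E + G'α2 + E G'β + E G_c β_c + ε

with Z1 ~ N(0,1), Z2 ~ Bernoulli(0.5), E ~ N(0,1), ε ~ N(0,1) and
α1 = 0.015 (a binary-E mode draws Bernoulli(0.5)).  Scenarios: with main
effects, every entry of α2 has magnitude 0.3 and an independent random
sign; without, α2 = 0.  Interaction effects: a configurable number of rare
variants (default 4 of 8) receive |β_j| = c with half the signs positive
(rounding up on odd counts); the first common variant receives β_c = 2c,
positive.  c = 0 is the null.  The analytic null trait variance is
0.25·Var(Z1) + 0.25·Var(Z2) + α1² + Var(ε) = 1.3125 + α1², the checked
recovery target.

Experiments fix one pool per experiment (its stream depends only on the
seed — in particular the same gene is used at every effect size of a power
sweep) and redraw genotypes, covariates, coefficient signs and noise every
replicate.  The tests then run exactly as they would on real data,
including the empirical-MAF rare/common split, so a borderline variant can
cross strata in a finite sample.

## Problem sizes and defaults

* n = 2000 samples, 1000 replicates for Type I error, at B = 1000
  permutations per replicate (the package's default study size; B = 10000
  is the production default for single-dataset analysis and a config knob
  in experiments).
* Power: 300 replicates per point over c ∈ {0.02, 0.04, 0.06, 0.08, 0.10},
  α = 0.05.
* Rejection rates are reported with exact (Clopper–Pearson) binomial 95%
  intervals.

## Known limitations

* The residual-permutation null is exact for exchangeable residuals and
  asymptotically valid after adjustment; at very small n with high-leverage
  covariates it can drift conservative.
* No asymptotic p-values: significance is permutation-only, so runtime
  scales with B and extreme p-values are bounded by 1/(B+1).
* No relatedness/kinship adjustment, no dosage (non-integer) input, no
  reference-panel imputation or phasing; binary-trait experiments are not
  built into the simulator (the test path itself supports binary traits).
* Bonferroni across SNP sets is emitted as an extra column, never applied
  to the raw p-values; region sizes of 10–30 SNPs are recommended to limit
  within-region collinearity.
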