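# Methods

## The model

`pleionet` infers a signed, directed network of genetic influences from a
population genotyped at a modest number of variant loci and measured for
two or more quantitative phenotypes that are partially pleiotropic —
sharing some genetic factors while retaining independent components. The
central assumption is that the spectrum of pairwise statistical epistasis
observed across phenotypes reflects one underlying network of
variant-to-variant influences, so jointly analysing several phenotypes can
disambiguate the direction of an interaction that any single phenotype
leaves ambiguous.

### Eigentraits

Phenotypes are mean-centered, scaled to unit sample SD (ddof = 1), and
factored by SVD, `P = U S Vᵀ`. The columns of `U` ("eigentraits") are
orthogonal composite phenotypes; with `k` equal to the number of
phenotypes nothing is truncated, so any effect estimated on the
eigentraits maps losslessly back to the original phenotypes by
multiplying with `diag(S) Vᵀ`. Working in the eigentrait basis decorrelates
the responses (which justifies treating the per-eigentrait regressions as
independent in error propagation) and improves covariate selection; the
influence coefficients themselves are invariant to this invertible
rotation. SVD signs are fixed by making each loading row's
largest-magnitude entry positive.

### Scans and the pairwise model

A single-locus OLS scan per eigentrait, `y = μ + xβ + ε` with `x` the
variant-allele probability, flags strong-effect variants: loci whose
statistic `|β|/SE` reaches a threshold (default 3.55, the permutation-EVD
calibrated p < 0.01 point for a five-locus, two-trait design; it can be
recalibrated for any design by `significance.single_locus_threshold`,
which fits a Gumbel distribution to per-permutation maxima of the scan
statistic over loci × eigentraits). Strong-effect variants enter
subsequent pairwise fits as covariates for the eigentrait that selected
them, excluding the tested pair itself.

Every locus pair is then fitted per eigentrait with main effects, a
product interaction term, and the covariates:

    y = μ + x₁β₁ + x₂β₂ + x₁x₂β₁₂ + Σ_c x_c β_c + ε.

Statistical epistasis is a significant `β₁₂`. The full coefficient
covariance `σ̂²(XᵀX)⁻¹` is retained for error propagation. Samples missing
a genotype at the pair or covariate loci are dropped listwise for that fit
only; rank-deficient designs (no double variants, duplicated columns) are
flagged inestimable rather than raised.

### Activity changes and influences

The interaction coefficients of a pair are reparametrized, jointly across
eigentraits, by two phenotype-independent *activity changes* `(δ₁, δ₂)` —
the inferred change in each variant's activity when the partner is
present — weighted per eigentrait by the variants' main effects:

    β₁₂ⱼ = δ₁ β₁ⱼ + δ₂ β₂ⱼ.

With two eigentraits the 2×2 system is solved exactly; with more it is
solved by least squares and the residual norm is reported as a
goodness-of-fit diagnostic for the assumed phenotype-independence of δ.
Directed *influence coefficients* then express each activity change as a
coefficient times the partner's total activity (baseline 1 plus its own
change):

    δ₁ = γ₁←₂ (1 + δ₂),   δ₂ = γ₂←₁ (1 + δ₁)
    ⇒ γ₁←₂ = δ₁ / (1 + δ₂),   γ₂←₁ = δ₂ / (1 + δ₁).

Negative γ is suppression, positive is enhancement. Two guards replace the
"inversion can blow up" caveat with testable behaviour: the solve is
flagged invalid when the main-effect matrix condition number exceeds 1e8,
and an influence direction is undefined when `|1 + δ|` falls below 1e-8.

### Error propagation

Standard errors of δ, γ and recomposed coefficients come from the delta
method on the OLS coefficient covariance. The δ Jacobian uses the
pseudoinverse differential `dδ = B⁺(db − dB δ) + (BᵀB)⁻¹ dBᵀ r` (with
residual `r`, zero in the exact two-trait case), chained through the
rational γ map. Cross-eigentrait coefficient covariance is taken as zero:
the responses are orthogonal by construction and fitted in separate
regressions. A generic central-finite-difference `propagate_variance`
(relative step 1e-6) covers arbitrary derived quantities and cross-checks
the analytic path; numerically negative variances are clamped to zero with
a warning. The linearization is certified against a 100,000-draw
Monte-Carlo oracle only on well-conditioned fits — where coefficient SEs
are small relative to the coefficients — because the γ ratio becomes
heavy-tailed near singular main-effect matrices and no finite-variance
summary matches a local expansion there; such fits are the condition
guard's job, not the SE's.

### Significance

All pairwise significance is empirical. For each pair, the two genotype
columns are permuted by one shared row shuffle ("tandem", preserving any
linkage between the markers) while phenotypes and covariates stay fixed,
and the entire fit → δ → γ → statistic pipeline is re-evaluated per
permutation (default 100,000; ≥1,000 is a reasonable desk-scale setting).
The test statistic is |coefficient|/SE throughout. Empirical p-values use
the (r+1)/(n+1) estimator and are never exactly zero; pairwise nulls are
never summarized by a fitted EVD, whose thin upper tail would overstate
significance relative to the empirical distribution.

The permutation stream depends only on the master seed, not the pair, so
permutation *t* applies the same shuffle to every pair. Besides making
results independent of pair processing order, this is what keeps the
averaged variant-to-phenotype statistic honest: a variant's main-effect
coefficient is nearly identical across the pair models it appears in, and
only a shared stream reproduces that cross-model correlation in the null.
With independent per-pair streams the null averages would be spuriously
stable and the averaged statistic roughly twice too significant (measured
as an all-null family-wise error of 0.55 at nominal 0.05).

Variant-to-variant influences are uniquely determined per pair;
variant-to-phenotype coefficients are recomposed onto the original
phenotypes per pair model and averaged over all models containing the
variant, with an RMS cross-model SE combination
`sqrt(mean variance)/sqrt(n_models)` (an independence approximation,
flagged in output metadata — models share samples, and the shared-stream
null is what absorbs the resulting optimism). The averaged statistic's
null is assembled per permutation index from the per-pair nulls.

One Holm step-down family covers every coefficient eligible to become a
network edge (all γ plus all averaged variant-to-phenotype effects), so
the step-down bounds the family-wise error of the network as a whole under
arbitrary dependence; splitting into two families would let the union
error approach twice the nominal level. Edges with adjusted p < α
(default 0.05) form the final directed network, exportable as TSV edge
list, GraphML or SIF ("activates"/"suppresses").

### Known limitations

* **Marginal permutation null.** Tandem permutation destroys the pair's
  main effects along with the interaction. Under the global null the
  procedure is exchangeability-exact (verified: uniform p-values,
  controlled FWER), but under the realistic partial null — real main
  effects, no influence — the permuted statistic is stochastically smaller
  than the H0 sampling distribution of the observed statistic (measured
  median 0.29 vs 0.67, which itself matches a half-normal, confirming the
  SEs). Influence p-values are therefore anticonservative in that regime.
* **Pairs in isolation.** Each pair is modelled separately; interaction
  terms of other pairs are omitted and partially absorbed into main
  effects (bias of order allele frequency × interaction coefficient).
  With several overlapping influences this can distort a pair's
  main-effect matrix enough to misattribute direction.
* **Identifiability requires complementarity.** When a pair's main-effect
  profiles are nearly parallel across eigentraits, δ is ill-determined;
  the condition guard and inflated SEs then (correctly) withhold an edge.
  A network is a map of resolvable influences, not of all influences.
* **Averaging can dilute.** A real effect present in one pair model can
  fall below significance when averaged over all models containing the
  variant.

## Synthetic data

The generator is the inference model run forward, which makes every
algebraic step testable against known truth: a sparse set of directed
influences γ implies δ per pair through the coupled relations above,
which implies interaction coefficients via the activity model; phenotypes
are the sum of all main effects, all implied pairwise interaction terms,
and Gaussian noise. Genotypes are independent Bernoulli loci (emulating
independent assortment in a haploid cross), with an optional
exchangeable-correlation linkage parameter (Gaussian copula) to stress the
linkage-preserving permutation.

Generator defaults, chosen once as the study conditions: two phenotypes;
variant-allele frequencies 0.5; main-effect magnitudes uniform in
[0.5, 1.5] with random signs (strong, well-measured perturbations of the
kind a designed cross targets); influence magnitudes uniform in [0.3, 0.8]
with random signs; noise SD 0.25 on the unit-variance phenotype scale.
Degenerate influence draws (|1 + δ| ≈ 0) are resampled. What the generator
does *not* emulate: selection-induced missing genotype classes, dominance
or multi-allelic loci, mechanistic pathway dynamics beyond the pairwise
effect model, and phenotype measurement structure (replicates, batch).
Passing recovery tests therefore certify the inference machinery under
the model's own assumptions, not robustness to their violation.

The expression generator plants two latent programs — one private to the
first phenotype, one shared — in gene blocks plus noise, reproducing the
structure where one phenotype corresponds to two expression modes and the
other to a single mode.

The two-variant suppression fixture (`simulate.suppression_fixture`) constructs
γ_{A←B} = −0.8, γ_{B←A} = 0 with distinct main-effect profiles; the
pipeline must infer a negative, significant influence of B on A.

## Expression mode analysis

Gene expression (genes × samples, log2 ratios vs. a reference strain) is
augmented with the phenotypes as extra rows — centered on the reference
value and scaled to SD 2 to match the expression scale — and factored by
SVD into global modes. Per mode, genes with weights ≥ 2 SD from the mean
(statistics over gene rows only; the appended phenotype rows are read-out
markers, not genes) form positive and negative gene sets. Enrichment
against flat annotation sets uses a one-sided Fisher exact test; GO-style
categories get a gene-name permutation FDR estimate (default 1,000 draws
at cutoff p < 1e-4), TF-target categories a Bonferroni factor for the
number of factors tested. The leading k mode sample-patterns can be fed
to the pairwise scan as composite phenotypes (already orthogonal, so
standardization and SVD are skipped); with k > 2 the activity solve runs
in least-squares mode and reports its residual. Adding modes without
adding samples dilutes significance — expected, since signal dimensions
grow while information does not.

## Numerical choices

* OLS through batched normal equations (designs here have ≤ ~10 well-scaled
  columns); normal-equation matrices with relative eigenvalue below 1e-9
  are treated as rank deficient.
* Condition-number guard 1e8 on the main-effect matrix; influence
  denominator tolerance 1e-8.
* Empirical p-values (r+1)/(n+1); Holm step-down via
  `statsmodels.stats.multitest`.
* Gumbel threshold fitting by maximum likelihood (`scipy.stats.gumbel_r`).
* One master seed; all child streams derived via `SeedSequence` from it
  and fixed labels, so a fit is bit-reproducible and pair-order
  independent.
* Benchmark problem sizes (50 recovery datasets at n = 500 with 1,000
  permutations per pair; 200 all-null datasets at n = 200 with 999
  permutations) are desk-scale settings that a single CPU completes in
  minutes.
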