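# pleionet

Directed genetic influence networks from populations measured for
multiple, partially pleiotropic quantitative phenotypes.

## The problem

Pairwise statistical epistasis — a significant interaction coefficient in
a two-locus regression — says that two variants interact, but not *how*:
for a single phenotype, "B suppresses A", "A enhances B" and several
other directed models can produce the same interaction coefficient. When
the same strains are measured for two or more phenotypes that share some
genetic factors but not all (partial pleiotropy), the interactions
observed across phenotypes jointly constrain the interpretation, because
a single underlying change in one variant's activity must explain every
phenotype's interaction at once.

`pleionet` implements that idea for a genotyped population (binary or
probabilistic variant calls at each locus) with ≥2 quantitative
phenotypes, and also for gene-expression SVD modes used as composite
phenotypes. It is aimed at statistical geneticists working with designed
crosses, segregant panels or mutant collections.

## The method in brief

1. Standardize phenotypes and rotate to orthogonal composite phenotypes
   ("eigentraits") by SVD, `P = U S Vᵀ` — lossless, since nothing is
   truncated.
2. Single-locus scans select strong-effect variants (statistic
   `|β|/SE ≥ 3.55` by default, a permutation-EVD calibrated p < 0.01) as
   covariates.
3. Every locus pair is fitted per eigentrait with main effects, a product
   interaction and the covariates:
   `y = μ + x₁β₁ + x₂β₂ + x₁x₂β₁₂ + Σ x_c β_c + ε`.
4. The interaction coefficients are reparametrized across eigentraits by
   activity changes δ with `β₁₂ⱼ = δ₁β₁ⱼ + δ₂β₂ⱼ` (exact 2×2 solve for two
   phenotypes, least squares for more), then as directed influence
   coefficients `γ₁←₂ = δ₁/(1+δ₂)`, `γ₂←₁ = δ₂/(1+δ₁)` — negative is
   suppression, positive enhancement.
5. SEs come from delta-method propagation of the OLS coefficient
   covariance; significance from tandem permutations of the pair's
   genotype columns with empirical p-values and a Holm step-down over all
   candidate edges; variant-to-phenotype effects are recomposed onto the
   original phenotypes and averaged over all pair models.
6. Edges with adjusted p < 0.05 form a signed directed network (TSV /
   GraphML / SIF).

See `docs/methods.md` for assumptions, guards and known limitations.

## Worked example

Simulate a 300-strain population with four biallelic loci and two planted
suppressive influences, then fit:

```python
from pleionet.simulate import simulate_genotypes, simulate_phenotypes, simulate_truth
from pleionet.model import InfluenceModel

truth = simulate_truth(loci=4, n_influences=2, seed=42)
print({f"{s}->{t}": round(g, 2) for (s, t), g in truth.gamma.items()})
# {'L2->L1': -0.34, 'L2->L3': -0.42}

G = simulate_genotypes(300, 4, seed=42)
pheno = simulate_phenotypes(G, truth, seed=42)
res = InfluenceModel(G, pheno).fit(n_perm_pair=5000, seed=0)
print(res.summary())
```

Abridged output:

```
covariates ET1: ['L1', 'L2', 'L3']
covariates ET2: ['L3', 'L4']

Variant-to-variant influences (negative = suppression)
source target   gamma      se   stat  p_raw    p_adj
    L2     L1 -0.4226  0.1587  2.663 0.0018   0.0198
    L1     L2  0.4637  1.4400  0.322 0.4513   1
    L2     L3 -0.6035  0.1509  4.000 0.0002   0.0040
    L3     L2 -0.3666  0.2675  1.370 0.0728   0.6551
    ...

network: 10 significant edge(s) at adjusted p < 0.05
```

Both planted influences are recovered with the correct (negative,
suppressive) sign and direction: `L2 → L1` (γ̂ = −0.42, adjusted
p = 0.02) and `L2 → L3` (γ̂ = −0.60, adjusted p = 0.004). The reverse
directions are correctly insignificant — note the reverse of `L2 → L1`
carries a ~9× larger standard error, which is how the solve expresses
that the data do not support that direction. The ten edges comprise the
two influences plus eight variant-to-phenotype effects.

The same analysis from the shell:

```sh
pleionet simulate --n 300 --loci 4 --influences 2 --seed 42 --out toy
pleionet run --genotypes toy.genotypes.tsv --phenotypes toy.phenotypes.tsv \
             --nperm-pair 5000 --seed 0 --out results/
```

which writes `results/{eigentraits,single_locus,pairwise,influences,effects}.tsv`,
`network.graphml`, `network.tsv` and `run.json` (config, seeds, versions).
`pleionet expression` runs the expression-mode variant: SVD modes of a
phenotype-augmented expression matrix, ±2 SD mode gene sets as GMT,
Fisher enrichment, and mode patterns exported as composite phenotypes for
`pleionet run`.

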