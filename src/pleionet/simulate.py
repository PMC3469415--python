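"""Synthetic populations with known ground-truth influence networks.

The generator is the inference model run forward: a sparse set of
directed influences gamma between loci implies activity changes delta
per pair (via the coupled influence relations), which imply interaction
coefficients b12 per pair per phenotype (activity model b12_j =
delta_1 b1_j + delta_2 b2_j).  Phenotypes are the pairwise regression
model plus Gaussian noise:

    y_ij = sum_v x_iv b_vj + sum_{u<v} x_iu x_iv b_uv,j + eps,  eps ~ N(0, sd)

Genotypes are independent Bernoulli loci (emulating independent
assortment in a cross) with an optional exchangeable-correlation linkage
parameter to stress the tandem-permutation null.

Defaults mirror the study design the method was developed on: 5-ish
biallelic loci near 50% variant frequency, two partially pleiotropic
phenotypes, noise SD 0.25 on the unit-variance phenotype scale, main
effects of order one, and influence magnitudes in [0.3, 0.8].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .influences import delta_from_gamma, interaction_from_activity
from .io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_truth",
    "simulate_phenotypes",
    "simulate_expression",
    "suppression_fixture",
]

#: default magnitude range for nonzero influence coefficients
GAMMA_RANGE = (0.3, 0.8)
#: default magnitude range for main (variant-to-phenotype) effects
BETA_RANGE = (0.5, 1.5)
#: default phenotype noise SD (unit-variance phenotype scale)
NOISE_SD = 0.25


def simulate_genotypes(n: int, loci: int, freqs=None, seed: int = 0,
                       linkage: float = 0.0) -> GenotypeMatrix:
    """Binary genotypes for ``n`` samples at ``loci`` independent loci.

    ``freqs`` are variant-allele frequencies (default 0.5 everywhere);
    ``linkage`` > 0 induces an exchangeable pairwise genotype correlation
    via a Gaussian copula, for stress-testing linkage-aware permutation.
    """
    freqs = np.full(loci, 0.5) if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.size != loci:
        raise ValueError("freqs length must equal loci")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9e]))
    if linkage == 0.0:
        X = (rng.random((n, loci)) < freqs).astype(float)
    else:
        cov = np.full((loci, loci), float(linkage))
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(loci), cov, size=n,
                                    method="cholesky")
        from scipy.stats import norm
        X = (z < norm.ppf(freqs)).astype(float)
    df = pd.DataFrame(X, index=[f"S{i + 1}" for i in range(n)],
                      columns=[f"L{j + 1}" for j in range(loci)])
    return GenotypeMatrix(df)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated population.

    ``gamma`` maps directed (source, target) locus pairs to influence
    coefficients; ``delta`` and ``beta12`` are derived from it through
    the forward influence/activity relations, so the generative model is
    internally consistent with the inference equations by construction.
    """

    locus_ids: list
    phenotype_ids: list
    beta: pd.DataFrame                  # loci x phenotypes main effects
    gamma: dict = field(default_factory=dict)   # (src, dst) -> float
    delta: dict = field(default_factory=dict)   # (l1, l2) -> (d1, d2)
    beta12: dict = field(default_factory=dict)  # (l1, l2) -> (k,) array
    noise_sd: float = NOISE_SD
    seed: int = 0

    def influenced_pairs(self):
        return sorted({tuple(sorted(k, key=str)) for k in self.gamma})


def _derive_pair(truth: SyntheticTruth, l1, l2, tol: float = 1e-6):
    """delta and beta12 for pair (l1, l2); None if degenerate."""
    g12 = truth.gamma.get((l2, l1), 0.0)   # influence of l2 on l1 (gamma_{1<-2})
    g21 = truth.gamma.get((l1, l2), 0.0)
    d1, d2 = delta_from_gamma(g12, g21)
    if not (np.isfinite(d1) and np.isfinite(d2)):
        return None
    if abs(1 + d1) < tol or abs(1 + d2) < tol:
        return None
    bmain = truth.beta.loc[[l1, l2]].to_numpy().T      # (k, 2)
    b12 = interaction_from_activity((d1, d2), bmain)
    return (d1, d2), b12


def simulate_truth(loci: int = 6, phenotypes: int = 2, n_influences: int = 4,
                   effect_range=GAMMA_RANGE, beta_range=BETA_RANGE,
                   noise_sd: float = NOISE_SD, seed: int = 0,
                   max_resample: int = 100) -> SyntheticTruth:
    """Random sparse ground-truth influence network.

    ``n_influences`` directed edges are drawn among ordered locus pairs
    with magnitudes in ``effect_range`` and random signs; main effects
    have magnitudes in ``beta_range`` with random signs.  Edge draws
    whose implied activity change is degenerate (|1 + delta| ~ 0) are
    resampled with a log entry.
    """
    if n_influences > loci * (loci - 1):
        raise ValueError("n_influences exceeds the number of directed pairs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7c]))
    locus_ids = [f"L{j + 1}" for j in range(loci)]
    pheno_ids = [f"P{m + 1}" for m in range(phenotypes)]
    beta = pd.DataFrame(
        rng.uniform(*beta_range, size=(loci, phenotypes))
        * rng.choice([-1.0, 1.0], size=(loci, phenotypes)),
        index=locus_ids, columns=pheno_ids,
    )
    directed = list(itertools.permutations(locus_ids, 2))
    truth = SyntheticTruth(locus_ids, pheno_ids, beta, noise_sd=noise_sd, seed=seed)
    for attempt in range(max_resample):
        chosen = rng.choice(len(directed), size=n_influences, replace=False)
        gamma = {
            directed[i]: float(rng.uniform(*effect_range) * rng.choice([-1.0, 1.0]))
            for i in chosen
        }
        truth.gamma = gamma
        derived = {}
        degenerate = False
        for l1, l2 in itertools.combinations(locus_ids, 2):
            res = _derive_pair(truth, l1, l2)
            if res is None:
                degenerate = True
                break
            derived[(l1, l2)] = res
        if not degenerate:
            break
        warnings.warn("degenerate influence draw resampled", stacklevel=2)
    else:
        raise RuntimeError("could not draw a non-degenerate influence network")
    for pair, (delta, b12) in derived.items():
        truth.delta[pair] = delta
        truth.beta12[pair] = b12
    return truth


def simulate_phenotypes(G: GenotypeMatrix, truth: SyntheticTruth,
                        seed: int = 0) -> PhenotypeTable:
    """Phenotypes from the forward model plus Gaussian noise."""
    X = G.values
    if list(G.locus_ids) != list(truth.locus_ids):
        raise ValueError("genotype loci do not match the truth's loci")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51]))
    Y = X @ truth.beta.to_numpy()
    idx = {l: i for i, l in enumerate(truth.locus_ids)}
    for (l1, l2), b12 in truth.beta12.items():
        Y += np.outer(X[:, idx[l1]] * X[:, idx[l2]], b12)
    Y += rng.normal(0.0, truth.noise_sd, size=Y.shape)
    return PhenotypeTable(pd.DataFrame(Y, index=G.sample_ids,
                                       columns=truth.phenotype_ids))


def simulate_expression(pheno: PhenotypeTable, n_genes: int = 5000,
                        genes_per_program: int = 300, effect: float = 1.0,
                        noise_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Synthetic expression with two latent programs tied to two phenotypes.

    The first phenotype is modelled as the sum of a private program and a
    shared program; the second phenotype reads out the shared program
    only.  One gene block loads on the private program, another on the
    shared one, the rest are noise.  The resulting SVD mode structure
    mirrors a design where one phenotype corresponds to two expression
    modes and the other to a single mode.
    """
    if pheno.data.shape[1] < 2:
        raise ValueError("need two phenotypes to define the latent programs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3d]))
    p1 = pheno.values[:, 0]
    p2 = pheno.values[:, 1]
    shared = (p2 - p2.mean()) / p2.std(ddof=1)
    private = p1 - p2
    private = (private - private.mean()) / private.std(ddof=1)
    n = len(shared)
    E = rng.normal(0.0, noise_sd, size=(n_genes, n))
    E[:genes_per_program] += effect * np.outer(
        rng.uniform(0.5, 1.5, genes_per_program) * rng.choice([-1, 1], genes_per_program),
        private)
    E[genes_per_program:2 * genes_per_program] += effect * np.outer(
        rng.uniform(0.5, 1.5, genes_per_program) * rng.choice([-1, 1], genes_per_program),
        shared)
    return pd.DataFrame(E, index=[f"G{i + 1}" for i in range(n_genes)],
                        columns=pheno.sample_ids)


def suppression_fixture(n: int = 400, gamma_suppression: float = -0.8,
                 noise_sd: float = NOISE_SD, seed: int = 11):
    """Two-variant, two-phenotype fixture with constructed suppression.

    Variant B suppresses variant A's activity (gamma_{A<-B} < 0) while A
    has no influence on B; both variants have distinct main-effect
    profiles so the main-effect matrix is well conditioned.  Returns
    (GenotypeMatrix, PhenotypeTable, SyntheticTruth).
    """
    locus_ids = ["A", "B"]
    pheno_ids = ["P1", "P2"]
    beta = pd.DataFrame([[1.0, 0.8], [-0.6, 0.9]], index=locus_ids,
                        columns=pheno_ids)
    truth = SyntheticTruth(locus_ids, pheno_ids, beta, noise_sd=noise_sd, seed=seed)
    truth.gamma = {("B", "A"): float(gamma_suppression)}
    delta, b12 = _derive_pair(truth, "A", "B")
    truth.delta[("A", "B")] = delta
    truth.beta12[("A", "B")] = b12
    G = simulate_genotypes(n, 2, seed=seed)
    G = GenotypeMatrix(G.data.set_axis(locus_ids, axis=1))
    pheno = simulate_phenotypes(G, truth, seed=seed)
    return G, pheno, truth
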