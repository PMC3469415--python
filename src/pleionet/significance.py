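"""Permutation-based significance calibration.

Two permutation schemes are used:

* single-locus threshold — whole-genotype row permutations; the maximum
  |beta|/SE over loci x eigentraits is collected per permutation and a
  Gumbel (extreme value) distribution fitted by maximum likelihood; its
  upper quantile is the multiple-test-corrected threshold for calling
  strong-effect variants.
* tandem pairwise null — for each tested pair, one shared row shuffle is
  applied to the two pair columns only (covariates and phenotypes fixed),
  which retains any linkage between the markers while breaking their
  association with phenotype.  The full pipeline (pairwise fit ->
  activity changes -> influences -> statistics) is re-evaluated per
  permutation to build empirical null distributions.  Pairwise p-values
  are always taken from the empirical distribution directly — never from
  a fitted EVD, whose thin upper tail would inflate significance.

Empirical p-values use the (r + 1) / (n + 1) estimator, so they are
never exactly zero.  Family-wise error is controlled by Holm's step-down
adjustment.  One master seed drives everything; per-pair child seeds are
derived deterministically from (seed, locus ids) so results do not
depend on the order in which pairs are processed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .influences import COND_MAX, DENOM_TOL, batched_influence_stats
from .scans import batched_pair_coefficients

__all__ = [
    "PermutationThreshold",
    "PairNull",
    "single_locus_threshold",
    "pairwise_null",
    "empirical_pvalue",
    "holm_adjust",
    "child_rng",
]

#: permutation chunk size bounding peak memory of the batched engine
_CHUNK = 20000


def child_rng(seed, *keys) -> np.random.Generator:
    """Deterministic child generator for (seed, *keys).

    String keys are hashed with CRC-32 so child streams depend only on
    the identifiers, not on processing order.
    """
    ent = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ent))


@dataclass
class PermutationThreshold:
    """Gumbel-calibrated threshold for the max single-locus statistic."""

    n_perm: int
    loc: float            # Gumbel location
    scale: float          # Gumbel scale
    alpha: float
    threshold: float      # EVD quantile at 1 - alpha
    seed: int
    maxima: np.ndarray = None

    def quantile(self, alpha: float) -> float:
        return float(stats.gumbel_r.ppf(1 - alpha, self.loc, self.scale))


def single_locus_threshold(G, Y, n_perm: int = 10000, alpha: float = 0.01,
                           seed: int = 0) -> PermutationThreshold:
    """EVD-calibrated significance threshold for single-locus scans.

    Per permutation the genotype rows are shuffled jointly (phenotypes
    fixed) and the maximum |beta|/SE over all loci and eigentraits is
    recorded; a Gumbel distribution fitted to the maxima gives the
    threshold at the 1 - alpha quantile.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gdf = G.data if hasattr(G, "data") else pd.DataFrame(G)
    X = gdf.to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    Yc = Y - Y.mean(axis=0)
    syy = (Yc**2).sum(axis=0)

    rng = child_rng(seed, "single-locus-evd")
    maxima = np.empty(n_perm)
    # |t| has closed form in the correlation r of permuted x with y:
    # t = |r| sqrt((n-2) / (1 - r^2)); Sxx is permutation invariant.
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.nan_to_num(Xc)  # missing contributes 0 to cross products
    norms = np.sqrt((Xc**2).sum(axis=0))
    for start in range(0, n_perm, _CHUNK):
        m = min(_CHUNK, n_perm - start)
        idx = np.argsort(rng.random((m, n)), axis=1)
        cross = np.einsum("pnl,nk->plk", Xc[idx], Yc)
        r = cross / (norms[None, :, None] * np.sqrt(syy)[None, None, :])
        r = np.clip(r, -0.999999999, 0.999999999)
        t = np.abs(r) * np.sqrt((n - 2) / (1 - r**2))
        maxima[start:start + m] = t.reshape(m, -1).max(axis=1)
    loc, scale = stats.gumbel_r.fit(maxima)
    thr = float(stats.gumbel_r.ppf(1 - alpha, loc, scale))
    return PermutationThreshold(n_perm, float(loc), float(scale), alpha, thr,
                                seed, maxima)


@dataclass
class PairNull:
    """Empirical null distributions for one pair's tandem permutations.

    ``gamma_stat`` holds |gamma|/SE statistics (n_perm, 2) with NaN for
    permutations where a direction was inestimable; ``vp_coef`` and
    ``vp_var`` hold the recomposed variant-to-phenotype coefficients and
    their variances (n_perm, 2, n_phenotypes) so that averaged-effect
    nulls can be assembled across pairs per permutation index.
    """

    pair: tuple
    n_perm: int
    seed: int
    gamma_stat: np.ndarray
    vp_coef: np.ndarray
    vp_var: np.ndarray
    n_invalid: int

    def gamma_null(self, direction: int) -> np.ndarray:
        return self.gamma_stat[:, direction]


def pairwise_null(G, Y, pair, covariates, n_perm: int, seed: int = 0,
                  dec=None, cond_max: float = COND_MAX,
                  denom_tol: float = DENOM_TOL) -> PairNull:
    """Tandem-permutation empirical nulls for one pair.

    Each permutation applies one shared row shuffle to the two pair
    genotype columns (covariates and eigentraits stay fixed) and re-runs
    the full pairwise fit -> activity -> influence pipeline.  If ``dec``
    (an EigentraitDecomposition) is given, variant-to-phenotype
    coefficients are recomposed onto the original phenotypes; otherwise
    eigentrait-scale coefficients are collected.

    The permutation stream depends only on (seed, n_perm), not on the
    pair: permutation t applies the same row shuffle to every pair.
    This keeps results independent of pair processing order and — more
    importantly — preserves, under the null, the strong cross-model
    correlation of a variant's main-effect coefficient across the pair
    models it appears in, which the averaged variant-to-phenotype
    statistic relies on.  (Samples excluded for a pair's missing
    genotypes use the shuffle induced on the remaining rows.)
    """
    from .scans import CovariateSet  # local import to avoid cycle at module load

    covariates = covariates or CovariateSet()
    gdf = G.data if hasattr(G, "data") else pd.DataFrame(G)
    Y = np.asarray(Y, dtype=float)
    k = Y.shape[1]
    cov_loci = sorted({l for j in range(k) for l in covariates.for_trait(j, exclude=pair)},
                      key=str)
    use = ~gdf[[pair[0], pair[1], *cov_loci]].isna().any(axis=1).to_numpy()
    x1 = gdf[pair[0]].to_numpy(dtype=float)[use]
    x2 = gdf[pair[1]].to_numpy(dtype=float)[use]
    Yu = Y[use]
    n = int(use.sum())
    n_full = len(gdf)
    cov_mats = []
    for j in range(k):
        cols = [np.ones(n)]
        for l in covariates.for_trait(j, exclude=pair):
            cols.append(gdf[l].to_numpy(dtype=float)[use][:, None].ravel())
        cov_mats.append(np.column_stack(cols))

    if dec is not None:
        M = dec.S[:, None] * dec.Vt          # (k, m)
        m_phen = M.shape[1]
    else:
        m_phen = k

    rng = child_rng(seed, "tandem-shared")
    gamma_stat = np.empty((n_perm, 2))
    vp_coef = np.empty((n_perm, 2, m_phen))
    vp_var = np.empty((n_perm, 2, m_phen))
    n_invalid = 0

    for start in range(0, n_perm, _CHUNK):
        mchunk = min(_CHUNK, n_perm - start)
        # shared stream over all samples; restriction to this pair's used
        # rows induces the pair's shuffle, identical at index t for all pairs
        R = rng.random((mchunk, n_full))
        idx = np.argsort(R[:, use], axis=1)
        res = batched_pair_coefficients(x1, x2, Yu, cov_mats, perm_idx=idx)
        stat, _, valid = batched_influence_stats(
            res["beta1"], res["beta2"], res["beta12"], res["cov3"],
            cond_max=cond_max, denom_tol=denom_tol)
        ok = res["ok"]
        stat[~ok] = np.nan
        n_invalid += int((~ok).sum())
        sl = slice(start, start + mchunk)
        gamma_stat[sl] = stat
        bmain = np.stack([res["beta1"], res["beta2"]], axis=1)      # (P, 2, k)
        vmain = np.stack([res["cov3"][:, :, 0, 0], res["cov3"][:, :, 1, 1]], axis=1)
        if dec is not None:
            vp_coef[sl] = np.einsum("pvk,km->pvm", bmain, M)
            vp_var[sl] = np.einsum("pvk,km->pvm", vmain, M**2)
        else:
            vp_coef[sl] = bmain
            vp_var[sl] = vmain
        vp_coef[sl][~ok] = np.nan
        vp_var[sl][~ok] = np.nan

    return PairNull(tuple(pair), n_perm, seed, gamma_stat, vp_coef, vp_var, n_invalid)


def empirical_pvalue(stat: float, null) -> float:
    """Empirical p-value (count(null >= stat) + 1) / (n_valid + 1).

    ``null`` is an array of permuted statistics; NaN entries (inestimable
    permutations) are excluded from the count.  The +1 correction keeps
    p-values strictly positive and valid.
    """
    null = np.asarray(null, dtype=float).ravel()
    valid = null[~np.isnan(null)]
    if valid.size == 0:
        raise ValueError("empirical null is empty (all permutations inestimable)")
    return float((np.sum(valid >= stat) + 1) / (valid.size + 1))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
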