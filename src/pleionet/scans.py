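"""Single-locus and pairwise interaction regressions on eigentraits.

The single-locus scan fits, per locus and per eigentrait,

    y_i = mu + x_i * beta + eps_i

and its test statistic |beta|/SE selects strong-effect variants used as
covariates in subsequent pairwise scans.  The pairwise model adds a
product interaction term and the per-eigentrait covariates (excluding
the pair itself):

    y_i = mu + x_i1 b1 + x_i2 b2 + x_i1 x_i2 b12 + sum_c x_ic bc + eps_i

Statistical epistasis is a significant interaction coefficient b12 in
this regression.  A vectorized engine (`batched_pair_coefficients`)
evaluates the same model under many tandem permutations of the pair
columns at once; the scalar `pairwise_fit` is a thin wrapper around a
batch of size one, so observed fits and permutation nulls share one
code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "single_locus_scan",
    "select_covariates",
    "pairwise_fit",
    "CovariateSet",
    "PairwiseFit",
]

#: relative eigenvalue floor below which a normal-equation matrix is
#: treated as rank deficient
_RANK_TOL = 1e-9


def single_locus_scan(G, Y) -> pd.DataFrame:
    """OLS of each eigentrait on each locus with an intercept.

    ``G`` is a GenotypeMatrix (or DataFrame), ``Y`` a samples x k
    eigentrait matrix.  Returns a long-form DataFrame with columns
    locus, eigentrait, intercept, beta, se, stat (= |beta|/SE).
    Constant loci are skipped with a warning; samples missing a locus's
    genotype are excluded for that locus only.
    """
    gdf = G.data if hasattr(G, "data") else pd.DataFrame(G)
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    rows = []
    for locus in gdf.columns:
        x = gdf[locus].to_numpy(dtype=float)
        use = ~np.isnan(x)
        xu, yu = x[use], Y[use]
        m = xu.size
        sxx = np.sum((xu - xu.mean()) ** 2)
        if sxx == 0:
            warnings.warn(f"locus {locus!r} is constant; skipped", stacklevel=2)
            continue
        xc = xu - xu.mean()
        beta = xc @ yu / sxx
        mu = yu.mean(axis=0) - beta * xu.mean()
        resid = yu - mu - np.outer(xu, beta)
        dof = m - 2
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(sigma2 / sxx)
        for j in range(k):
            stat = np.abs(beta[j]) / se[j] if se[j] > 0 else np.inf
            rows.append((locus, j, mu[j], beta[j], se[j], stat, m))
    return pd.DataFrame(
        rows, columns=["locus", "eigentrait", "intercept", "beta", "se", "stat", "n_used"]
    )


@dataclass
class CovariateSet:
    """Strong-effect variants, listed separately for each eigentrait."""

    per_trait: dict = field(default_factory=dict)  # eigentrait index -> [locus ids]
    threshold: float = 3.55

    def for_trait(self, j: int, exclude=()) -> list:
        return [l for l in self.per_trait.get(j, []) if l not in set(exclude)]


def select_covariates(scan: pd.DataFrame, threshold: float = 3.55) -> CovariateSet:
    """Loci whose single-locus statistic meets ``threshold``, per eigentrait.

    The default 3.55 is the permutation-calibrated p<0.01 cutoff for the
    max |beta|/SE statistic; `significance.single_locus_threshold`
    recalibrates it for other designs.
    """
    per_trait: dict = {}
    for j, sub in scan.groupby("eigentrait"):
        per_trait[int(j)] = list(sub.loc[sub["stat"] >= threshold, "locus"])
    return CovariateSet(per_trait, threshold)


@dataclass
class PairwiseFit:
    """Pairwise interaction regression results, one block per eigentrait."""

    pair: tuple
    k: int
    beta1: np.ndarray          # (k,) main effect of locus 1
    beta2: np.ndarray          # (k,) main effect of locus 2
    beta12: np.ndarray         # (k,) interaction coefficient
    cov3: np.ndarray           # (k, 3, 3) covariance of (b1, b2, b12) per eigentrait
    theta: list                # per-eigentrait full coefficient vectors
    cov_full: list             # per-eigentrait full coefficient covariance
    param_names: list          # per-eigentrait coefficient labels
    sigma2: np.ndarray         # (k,) residual variances
    n_used: int
    covariates: list           # per-eigentrait covariate locus lists
    estimable: bool = True
    note: str = ""


def _pair_columns(G, pair):
    gdf = G.data if hasattr(G, "data") else pd.DataFrame(G)
    l1, l2 = pair
    return gdf[l1].to_numpy(dtype=float), gdf[l2].to_numpy(dtype=float), gdf


def batched_pair_coefficients(x1, x2, Y, cov_mats, perm_idx=None):
    """Fit the pairwise model under a batch of tandem permutations.

    Parameters
    ----------
    x1, x2 : (n,) genotype columns of the tested pair (no missing values).
    Y : (n, k) eigentrait matrix.
    cov_mats : list of k design blocks (n, c_j), each including the
        intercept column, holding the per-eigentrait covariates.
    perm_idx : (P, n) int array of row permutations applied to x1 and x2
        jointly (tandem), or None for the observed (identity) fit.

    Returns
    -------
    dict with beta1, beta2, beta12 (each (P, k)), cov3 (P, k, 3, 3),
    sigma2 (P, k), ok (P,) bool mask of estimable fits, plus theta/cov
    lists with full per-eigentrait results.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if perm_idx is None:
        perm_idx = np.arange(n)[None, :]
    P = perm_idx.shape[0]

    x1p = x1[perm_idx]                      # (P, n)
    x2p = x2[perm_idx]
    V = np.stack([x1p, x2p, x1p * x2p], axis=2)   # (P, n, 3)

    beta1 = np.empty((P, k))
    beta2 = np.empty((P, k))
    beta12 = np.empty((P, k))
    cov3 = np.empty((P, k, 3, 3))
    sigma2 = np.empty((P, k))
    ok = np.ones(P, dtype=bool)
    theta_all, cov_all = [], []

    for j in range(k):
        C = cov_mats[j]                     # (n, c)
        c = C.shape[1]
        p = c + 3
        y = Y[:, j]

        A = np.empty((P, p, p))
        A[:, :c, :c] = C.T @ C
        A12 = np.einsum("nc,pnv->pcv", C, V)
        A[:, :c, c:] = A12
        A[:, c:, :c] = A12.transpose(0, 2, 1)
        A[:, c:, c:] = np.einsum("pnu,pnv->puv", V, V)

        rhs = np.empty((P, p))
        rhs[:, :c] = C.T @ y
        rhs[:, c:] = np.einsum("pnv,n->pv", V, y)

        # rank guard: near-singular normal equations -> inestimable fit
        eig = np.linalg.eigvalsh(A)
        bad = eig[:, 0] <= _RANK_TOL * np.maximum(eig[:, -1], 1.0)
        if bad.any():
            ok &= ~bad
            A[bad] = np.eye(p)
        Ainv = np.linalg.inv(A)
        th = np.einsum("pij,pj->pi", Ainv, rhs)
        rss = np.maximum(y @ y - np.einsum("pi,pi->p", th, rhs), 0.0)
        dof = n - p
        s2 = rss / dof
        covf = s2[:, None, None] * Ainv

        beta1[:, j] = th[:, c]
        beta2[:, j] = th[:, c + 1]
        beta12[:, j] = th[:, c + 2]
        sl = slice(c, c + 3)
        cov3[:, j] = covf[:, sl, sl]
        sigma2[:, j] = s2
        theta_all.append(th)
        cov_all.append(covf)

    return {
        "beta1": beta1, "beta2": beta2, "beta12": beta12, "cov3": cov3,
        "sigma2": sigma2, "ok": ok, "theta": theta_all, "cov": cov_all,
    }


def pairwise_fit(G, Y, pair, covariates: CovariateSet | None = None) -> PairwiseFit:
    """OLS pairwise interaction fit for one locus pair on all eigentraits.

    Samples missing a genotype at either pair locus or at any covariate
    locus are excluded listwise for this fit only.  A rank-deficient
    design (e.g. no double-variant samples, or identical pair columns)
    yields ``estimable=False`` rather than an exception.
    """
    covariates = covariates or CovariateSet()
    x1, x2, gdf = _pair_columns(G, pair)
    Y = np.asarray(Y, dtype=float)
    k = Y.shape[1]

    cov_loci = sorted({l for j in range(k) for l in covariates.for_trait(j, exclude=pair)},
                      key=str)
    need = [pair[0], pair[1], *cov_loci]
    use = ~gdf[need].isna().any(axis=1).to_numpy()
    x1u, x2u, Yu = x1[use], x2[use], Y[use]
    n_used = int(use.sum())

    if np.array_equal(x1u, x2u):
        return PairwiseFit(pair, k, *(np.full(k, np.nan),) * 3,
                           np.full((k, 3, 3), np.nan), [], [], [],
                           np.full(k, np.nan), n_used, [], estimable=False,
                           note="identical genotype columns")

    cov_lists = [covariates.for_trait(j, exclude=pair) for j in range(k)]
    cov_mats, names = [], []
    for j in range(k):
        cols = [np.ones(n_used)]
        for l in cov_lists[j]:
            cols.append(gdf[l].to_numpy(dtype=float)[use])
        cov_mats.append(np.column_stack(cols))
        names.append(["intercept", *[f"cov:{l}" for l in cov_lists[j]],
                      f"main:{pair[0]}", f"main:{pair[1]}", "interaction"])

    res = batched_pair_coefficients(x1u, x2u, Yu, cov_mats)
    if not res["ok"][0]:
        return PairwiseFit(pair, k, *(np.full(k, np.nan),) * 3,
                           np.full((k, 3, 3), np.nan), [], [], [],
                           np.full(k, np.nan), n_used, cov_lists, estimable=False,
                           note="inestimable interaction (rank-deficient design)")
    return PairwiseFit(
        pair, k,
        res["beta1"][0], res["beta2"][0], res["beta12"][0], res["cov3"][0],
        [t[0] for t in res["theta"]], [cf[0] for cf in res["cov"]], names,
        res["sigma2"][0], n_used, cov_lists,
    )
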