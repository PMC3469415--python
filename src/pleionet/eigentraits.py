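"""Composite orthogonal phenotypes ("eigentraits") by SVD.

Phenotypes are mean-centered and scaled to unit sample standard deviation,
then factored as P = U S Vt.  The columns of U are the eigentraits:
uncorrelated composite phenotypes on which all regression modelling is
performed.  Because the decomposition is full rank (k = number of
phenotypes), effect estimates on eigentraits can be mapped back to the
original phenotypes without any loss of fit quality by multiplying with
diag(S) Vt.

Sign convention: the largest-magnitude loading of each right singular
vector is made positive, which removes the SVD sign ambiguity and makes
output reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenotypeTable

__all__ = ["EigentraitDecomposition", "standardize", "decompose", "recompose_effects"]


def standardize(pheno) -> pd.DataFrame:
    """Mean-center and scale each phenotype to unit sample SD (ddof=1).

    Raises ``ValueError`` naming the phenotype if a column has zero
    variance, and if any values are missing (impute or drop first).
    """
    df = pheno.data if isinstance(pheno, PhenotypeTable) else pd.DataFrame(pheno)
    if df.isna().any().any():
        raise ValueError("missing phenotype values: impute or drop before standardizing")
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance phenotype(s): {list(zero.index)}")
    return (df - df.mean()) / sd


@dataclass
class EigentraitDecomposition:
    """Full SVD of the standardized phenotype matrix, P = U S Vt."""

    U: np.ndarray           # samples x k, orthonormal columns (eigentraits)
    S: np.ndarray           # k singular values, descending
    Vt: np.ndarray          # k x phenotypes, orthonormal rows (loadings)
    phenotype_ids: list
    sample_ids: list

    @property
    def k(self) -> int:
        return len(self.S)

    @property
    def eigentrait_ids(self) -> list:
        return [f"ET{i + 1}" for i in range(self.k)]

    def reconstruct(self) -> np.ndarray:
        return self.U @ np.diag(self.S) @ self.Vt


def decompose(P: pd.DataFrame) -> EigentraitDecomposition:
    """Exact SVD of a standardized phenotype matrix (samples > phenotypes).

    Rank-deficient input is allowed; zero singular values are retained so
    that k always equals the number of phenotypes.
    """
    n, k = P.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than phenotypes ({k})")
    U, S, Vt = np.linalg.svd(P.to_numpy(dtype=float), full_matrices=False)
    # deterministic sign: largest-|loading| entry of each row of Vt positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return EigentraitDecomposition(U, S, Vt, list(P.columns), list(P.index))


def recompose_effects(coeffs: np.ndarray, dec: EigentraitDecomposition) -> np.ndarray:
    """Map effect estimates on eigentraits back to the original phenotypes.

    ``coeffs`` has one row per predictor (e.g. variant) and one column per
    eigentrait; the returned matrix has one column per phenotype.  Since
    phenotype m is sum_j U_j S_j Vt[j, m], a coefficient vector b on the
    eigentraits maps to b diag(S) Vt on the phenotypes, and by linearity of
    least squares this equals the coefficients from regressing each
    standardized phenotype directly.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != dec.k:
        raise ValueError(
            f"coefficient matrix has {coeffs.shape[-1]} eigentrait columns, "
            f"decomposition has {dec.k}"
        )
    return coeffs @ (dec.S[:, None] * dec.Vt)


def recompose_variances(variances: np.ndarray, dec: EigentraitDecomposition) -> np.ndarray:
    """Propagate per-eigentrait coefficient variances through recomposition.

    The map is linear with weights S_j Vt[j, m]; eigentrait regressions are
    treated as independent (orthogonal responses), so variances combine as
    a weighted sum with squared weights.
    """
    variances = np.asarray(variances, dtype=float)
    return variances @ (dec.S[:, None] * dec.Vt) ** 2
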