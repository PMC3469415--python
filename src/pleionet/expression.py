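"""Global expression modes by SVD, mode gene sets and enrichment.

Gene expression (genes x samples, log2 ratios vs. a reference strain) is
augmented with the quantitative phenotypes as extra rows — each centered
on the reference strain's value and scaled to a target SD (default 2) to
match the origin and scale of the expression data — and factored by SVD
into global expression patterns ("modes").  Because two phenotype rows
are appended to thousands of gene rows, their contribution to the modes
is negligible; the phenotype weights merely read out which modes each
phenotype corresponds to.

Per mode, genes whose weights lie two or more SDs from the mean (SD
computed over gene rows only) form positive and negative gene sets,
which are queried for annotation enrichment with a one-sided Fisher
exact test.  GO-style categories get a gene-name permutation FDR
estimate at a p cutoff; transcription-factor target categories get a
Bonferroni factor for the number of factors tested.  The leading mode
sample-patterns can also serve as composite phenotypes for the pairwise
influence scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSets, ExpressionMatrix, PhenotypeTable

__all__ = [
    "ExpressionModes",
    "ModeGeneSet",
    "EnrichmentResult",
    "augment_with_phenotypes",
    "decompose_expression",
    "mode_gene_sets",
    "enrichment",
    "modes_as_phenotypes",
]


def augment_with_phenotypes(expr: ExpressionMatrix, pheno: PhenotypeTable,
                            reference_sample=None, target_sd: float = 2.0) -> pd.DataFrame:
    """Append phenotype rows to the expression matrix, rescaled to match it.

    Each phenotype is re-centered on the reference strain's value (the
    phenotype mean over expression samples if ``reference_sample`` is
    None) and scaled to sample SD ``target_sd``, mirroring the log2-ratio
    origin and scale of the expression rows.  Gene rows pass through
    unchanged.
    """
    samples = expr.sample_ids
    missing = [s for s in samples if s not in set(pheno.sample_ids)]
    if missing:
        raise ValueError(f"phenotype values missing for expression sample(s): {missing}")
    sub = pheno.data.loc[samples]
    if reference_sample is not None:
        origin = pheno.data.loc[reference_sample]
    else:
        origin = sub.mean()
    centered = sub - origin
    scaled = centered / centered.std(ddof=1) * target_sd
    extra = scaled.T
    extra.index = [str(c) for c in pheno.phenotype_ids]
    return pd.concat([expr.data, extra], axis=0)


@dataclass
class ExpressionModes:
    """SVD modes of the (phenotype-augmented) expression matrix."""

    sample_patterns: np.ndarray     # modes x samples (right singular vectors)
    gene_weights: np.ndarray        # genes x modes (left singular vectors)
    singular_values: np.ndarray
    variance_fraction: np.ndarray   # squared singular value / total
    gene_ids: list                  # gene rows (annotation-eligible)
    phenotype_weights: pd.DataFrame  # appended phenotype rows x modes
    sample_ids: list


def decompose_expression(matrix: pd.DataFrame, phenotype_rows=()) -> ExpressionModes:
    """SVD of a rows x samples matrix into global modes.

    ``phenotype_rows`` names appended non-gene rows; their weights are
    reported separately and excluded from gene-set statistics.  The same
    deterministic sign convention as the eigentrait decomposition is
    applied (largest-|entry| of each sample pattern made positive).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(len(S)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    frac = S**2 / np.sum(S**2)
    phen = set(map(str, phenotype_rows))
    is_gene = np.array([str(r) not in phen for r in matrix.index])
    gene_ids = [r for r in matrix.index if str(r) not in phen]
    pweights = pd.DataFrame(
        U[~is_gene], index=[r for r in matrix.index if str(r) in phen],
        columns=[f"Mode{j + 1}" for j in range(len(S))],
    )
    return ExpressionModes(Vt, U[is_gene], S, frac, gene_ids, pweights,
                           list(matrix.columns))


@dataclass
class ModeGeneSet:
    """Genes loading beyond k SDs on one mode, split by weight sign."""

    mode: int          # 1-based mode index
    direction: str     # "positive" | "negative"
    genes: list


def mode_gene_sets(modes: ExpressionModes, k_sd: float = 2.0) -> list:
    """Two gene sets per mode: weights >= k_sd SDs above/below the mean.

    Mean and SD are computed over that mode's gene weights only
    (appended phenotype rows are markers, not genes).
    """
    out = []
    genes = np.asarray(modes.gene_ids)
    for j in range(len(modes.singular_values)):
        w = modes.gene_weights[:, j]
        mu, sd = w.mean(), w.std(ddof=1)
        extreme = np.abs(w - mu) >= k_sd * sd
        pos = genes[extreme & (w > mu)]
        neg = genes[extreme & (w < mu)]
        out.append(ModeGeneSet(j + 1, "positive", list(pos)))
        out.append(ModeGeneSet(j + 1, "negative", list(neg)))
    return out


@dataclass
class EnrichmentResult:
    """One term's enrichment in one gene set."""

    term: str
    description: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    p_adjusted: float = np.nan  # Bonferroni (TF categories only)


def _fisher_p(overlap: int, set_size: int, term_size: int, universe_size: int) -> float:
    # one-sided (enrichment) Fisher exact = hypergeometric upper tail
    return float(stats.hypergeom.sf(overlap - 1, universe_size, term_size, set_size))


def enrichment(gene_set, universe, annotations: AnnotationSets, category: str = "GO",
               p_cutoff: float = 1e-4, n_perm: int = 1000, seed: int = 0):
    """One-sided Fisher enrichment of a mode gene set against annotations.

    Returns (results, fdr) where ``fdr`` is a gene-name permutation
    estimate of the false discovery rate at ``p_cutoff`` for GO-style
    categories (None otherwise).  TF-target categories instead get
    Bonferroni-adjusted p-values for the number of factors tested.
    Terms disjoint from the universe are skipped with a warning; an
    empty gene set yields an empty result list.
    """
    genes = [g for g in (gene_set.genes if isinstance(gene_set, ModeGeneSet) else gene_set)]
    universe = list(universe)
    uset = set(universe)
    gset = set(genes) & uset
    if not gset:
        return [], None

    terms = {}
    for term, members in annotations.sets.items():
        inter = members & uset
        if not inter:
            warnings.warn(f"term {term!r} disjoint from universe; skipped", stacklevel=2)
            continue
        terms[term] = inter

    N = len(uset)
    results = []
    for term, members in terms.items():
        overlap = len(gset & members)
        p = _fisher_p(overlap, len(gset), len(members), N)
        desc = annotations.meta.get(term, {}).get("description", "")
        results.append(EnrichmentResult(term, desc, overlap, len(gset),
                                        len(members), N, p))
    results.sort(key=lambda r: r.p)

    if category.upper() == "TF":
        m = len(terms)
        for r in results:
            r.p_adjusted = min(1.0, r.p * m)
        return results, None

    # GO-style: permutation of gene names -> FDR estimate at p_cutoff
    n_hits = sum(r.p <= p_cutoff for r in results)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x60]))
    null_hits = np.empty(n_perm)
    univ_arr = np.asarray(universe, dtype=object)
    size = len(gset)
    for b in range(n_perm):
        draw = set(rng.choice(univ_arr, size=size, replace=False))
        null_hits[b] = sum(
            _fisher_p(len(draw & members), size, len(members), N) <= p_cutoff
            for members in terms.values()
        )
    fdr = float(null_hits.mean() / max(n_hits, 1))
    return results, fdr


def modes_as_phenotypes(modes: ExpressionModes, k: int) -> pd.DataFrame:
    """First k mode sample-patterns as a composite-phenotype matrix.

    The returned samples x k DataFrame feeds the pairwise influence scan
    directly: the patterns are already orthogonal, so the usual
    standardize-and-decompose step is skipped (flagged via the attribute
    ``already_orthogonal``).
    """
    rank = int(np.sum(modes.singular_values > 0))
    if k > rank or k > len(modes.sample_ids):
        raise ValueError(f"k={k} exceeds the decomposition rank ({rank})")
    df = pd.DataFrame(
        modes.sample_patterns[:k].T, index=modes.sample_ids,
        columns=[f"Mode{j + 1}" for j in range(k)],
    )
    df.attrs["already_orthogonal"] = True
    return df
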