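"""Readers, writers and validated containers for the package's tabular inputs.

Four kinds of input are handled:

* genotypes — samples x loci, variant-allele probabilities in [0, 1]
  (binary 0/1 for a fully genotyped cross); 0 codes the reference allele,
  1 the variant,
* quantitative phenotypes — samples x phenotypes, real valued,
* gene expression — genes x samples, log2 ratios relative to a reference
  strain,
* flat annotation sets (GMT) — term -> gene set, for enrichment queries.

All tabular formats are TSV by default with comma autodetected from the
header line.  Containers are thin dataclasses around :class:`pandas.DataFrame`
that validate identifiers and value ranges on construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "ExpressionMatrix",
    "AnnotationSets",
    "read_genotypes",
    "read_phenotypes",
    "read_expression",
    "read_annotations",
    "write_genotypes",
    "write_phenotypes",
]

#: significant digits preserved by the text writers (round-trip guarantee)
FLOAT_DIGITS = 12


class ValidationError(ValueError):
    """Input fails a structural or range invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dups}")


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of variant-allele probabilities.

    0 = reference allele, 1 = variant; intermediate values are
    probabilities (e.g. imputed genotypes).  NaN marks missing calls.
    """

    data: pd.DataFrame
    reference_note: str = "0 = reference allele (wild-type), 1 = variant"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "locus")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValidationError(
                f"need >=2 samples and >=1 locus, got {self.data.shape}"
            )
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            r, c = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"genotype value {vals[r, c]} outside [0, 1] at sample "
                f"{self.data.index[r]!r}, locus {self.data.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()


@dataclass
class PhenotypeTable:
    """Samples x phenotypes table of raw (pre-standardization) measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "phenotype")
        if not self.pleiotropy_available:
            warnings.warn(
                "single phenotype: pleiotropy unavailable, influence "
                "inference disabled",
                stacklevel=3,
            )

    @property
    def pleiotropy_available(self) -> bool:
        """Influence inference needs >=2 partially pleiotropic phenotypes."""
        return self.data.shape[1] >= 2

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def phenotype_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()


@dataclass
class ExpressionMatrix:
    """Genes (rows) x samples (columns), log2 ratios vs. a reference strain."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class AnnotationSets:
    """Flat term -> gene-set mapping with per-term metadata.

    ``category`` distinguishes e.g. GO biological-process terms from
    transcription-factor target sets, which receive different multiple-
    testing treatment downstream.
    """

    sets: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"annotation term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term):
        return self.sets[term]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_numeric_table(path, what: str) -> pd.DataFrame:
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    out = {}
    na_tokens = {"", "NA", "NaN", "nan", "N/A", "na"}
    for col in raw.columns:
        cells = raw[col]
        is_na = cells.isna() | cells.astype(str).str.strip().isin(na_tokens)
        num = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = num.isna() & ~is_na
        if bad.any():
            row = cells.index[bad.to_numpy()][0]
            raise ValidationError(
                f"malformed numeric cell {cells[bad].iloc[0]!r} in {what} file "
                f"at row {row!r}, column {col!r}"
            )
        out[col] = num
    return pd.DataFrame(out, index=raw.index)


def read_genotypes(path) -> GenotypeMatrix:
    """Read a samples x loci genotype table (TSV/CSV, NA allowed)."""
    return GenotypeMatrix(_read_numeric_table(path, "genotype"))


def read_phenotypes(path) -> PhenotypeTable:
    """Read a samples x phenotypes table; column order is preserved."""
    return PhenotypeTable(_read_numeric_table(path, "phenotype"))


def read_expression(path, population_samples=None) -> ExpressionMatrix:
    """Read a genes x samples expression table of log2 ratios.

    Duplicate gene rows (e.g. duplicated microarray probes) are averaged
    on the log2 scale.  If ``population_samples`` is given, every
    expression sample must occur in it.
    """
    df = _read_numeric_table(path, "expression")
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    if population_samples is not None:
        unmatched = [s for s in df.columns if s not in set(population_samples)]
        if unmatched:
            raise ValidationError(
                f"expression sample(s) not in population: {unmatched}"
            )
    return ExpressionMatrix(df)


def read_annotations(path) -> AnnotationSets:
    """Read a GMT file (term, description, then tab-separated gene ids)."""
    sets: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term, desc, genes = fields[0], fields[1], set(fields[2:]) - {""}
            if term in sets:
                warnings.warn(
                    f"duplicate GMT term {term!r}: gene sets merged by union",
                    stacklevel=2,
                )
                sets[term] |= genes
            else:
                sets[term] = genes
                meta[term] = {"description": desc, "category": "unspecified"}
    if not sets:
        warnings.warn("empty GMT file: no annotation sets loaded", stacklevel=2)
    return AnnotationSets(sets, meta)


def _write_table(df: pd.DataFrame, path, index_label: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format=f"%.{FLOAT_DIGITS}g")


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    _write_table(geno.data, path, "sample")


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    _write_table(pheno.data, path, "sample")


def align_samples(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Inner-join genotype and phenotype tables on sample id.

    Returns aligned (GenotypeMatrix, PhenotypeTable) in genotype-file
    sample order; pairing is by identifier, so row shuffles of either
    input do not change the result.
    """
    shared = [s for s in geno.sample_ids if s in set(pheno.sample_ids)]
    if len(shared) < 2:
        raise ValidationError("fewer than 2 shared samples between genotype and phenotype tables")
    return (
        GenotypeMatrix(geno.data.loc[shared], geno.reference_note),
        PhenotypeTable(pheno.data.loc[shared]),
    )
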