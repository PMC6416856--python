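"""Gene x phenotype membership from a WormBase simplemine export.

Four phenotype ontology terms resembling life-history traits of large,
slow-growing animals — "long", "slow growth", "extended life span" and
"reduced brood size" — are looked up as exact tokens in each gene's
mutant-phenotype and RNAi-phenotype lists, and the exclusive (exact-subset)
intersections among them are counted, UpSet-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TERMS",
    "PhenotypeMatrix",
    "IntersectionCounts",
    "parse_simplemine",
    "intersection_counts",
    "write_upset_matrix",
    "read_upset_matrix",
]

DEFAULT_TERMS = ("long", "slow growth", "extended life span", "reduced brood size")
DEFAULT_DELIMITERS = ",;|"
_NA_TOKENS = {"", "n.a.", "na", "n/a", "none", "nan"}


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Boolean gene x term membership. ``flags`` is indexed by gene id."""

    flags: pd.DataFrame  # bool columns, one per term
    total_genes: int

    def __post_init__(self):
        if self.flags.index.duplicated().any():
            dupes = self.flags.index[self.flags.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:10]}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.flags.columns)

    @property
    def total_with_any(self) -> int:
        return int(self.flags.any(axis=1).sum())

    @property
    def marginal_totals(self) -> dict[str, int]:
        return {t: int(self.flags[t].sum()) for t in self.flags.columns}


@dataclass(frozen=True)
class IntersectionCounts:
    """Exclusive subset counts over the phenotype terms.

    ``counts`` maps each nonempty frozenset of terms to the number of genes
    whose flag set equals exactly that subset.
    """

    counts: dict
    total_with_any: int
    total_genes: int

    @property
    def n_exactly_one(self) -> int:
        return sum(v for k, v in self.counts.items() if len(k) == 1)

    def n_with_all(self, terms) -> int:
        return self.counts.get(frozenset(terms), 0)


def _find_column(columns, candidates):
    lowered = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    for low, orig in lowered.items():
        if any(cand in low for cand in candidates):
            return orig
    return None


def _tokenize(cell: str, delimiters: str) -> set[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    text = str(cell)
    for d in delimiters[1:]:
        text = text.replace(d, delimiters[0])
    tokens = {t.strip().lower() for t in text.split(delimiters[0])}
    return {t for t in tokens if t not in _NA_TOKENS}


def parse_simplemine(
    source: str | Path | pd.DataFrame,
    terms=DEFAULT_TERMS,
    delimiters: str = DEFAULT_DELIMITERS,
) -> PhenotypeMatrix:
    """Flag phenotype-term membership for every gene in a simplemine export.

    A gene is flagged for a term when the term appears as an exact token
    (case-insensitive, whitespace-trimmed) in the delimiter-separated list
    of either its mutant-phenotype or RNAi-phenotype column. Substring hits
    do not count ("long" never matches "elongated"). Genes whose phenotype
    cells are empty or "N.A." simply get all-false flags and still count
    toward ``total_genes``.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", dtype=str)
    else:
        df = source.copy()
    gene_col = _find_column(
        df.columns,
        ["wormbase gene id", "wbgene", "gene wb id", "your input", "gene", "gene id"],
    )
    if gene_col is None:
        gene_col = df.columns[0]
    pheno_cols = [
        c
        for c in df.columns
        if "phenotype" in str(c).lower() and c != gene_col
    ]
    if not pheno_cols:
        raise ValueError("no phenotype column found in simplemine export")

    genes = df[gene_col].astype(str).str.strip()
    if genes.duplicated().any():
        dupes = genes[genes.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in export: {dupes[:10]}")

    term_keys = [t.strip().lower() for t in terms]
    flag_data = np.zeros((len(df), len(terms)), dtype=bool)
    for col in pheno_cols:
        for i, cell in enumerate(df[col].tolist()):
            tokens = _tokenize(cell, delimiters)
            if not tokens:
                continue
            for j, key in enumerate(term_keys):
                if key in tokens:
                    flag_data[i, j] = True
    flags = pd.DataFrame(flag_data, index=pd.Index(genes, name="gene_id"),
                         columns=list(terms))
    return PhenotypeMatrix(flags=flags, total_genes=len(df))


def intersection_counts(matrix: PhenotypeMatrix) -> IntersectionCounts:
    """Exclusive (exact-subset) gene counts for every nonempty term subset."""
    terms = matrix.terms
    counts: dict = {}
    arr = matrix.flags.to_numpy(bool)
    if arr.size:
        keys, key_counts = np.unique(arr, axis=0, return_counts=True)
        for key, n in zip(keys, key_counts):
            subset = frozenset(t for t, k in zip(terms, key) if k)
            if subset:
                counts[subset] = int(n)
    total_any = sum(counts.values())
    return IntersectionCounts(
        counts=counts,
        total_with_any=total_any,
        total_genes=matrix.total_genes,
    )


def write_upset_matrix(matrix: PhenotypeMatrix, path: str | Path) -> Path:
    """Write gene id + one 0/1 column per term (UpSet input format).

    Only genes with at least one flag are written, matching the published
    intersection spreadsheet.
    """
    path = Path(path)
    out = matrix.flags[matrix.flags.any(axis=1)].astype(int).reset_index()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_upset_matrix(path: str | Path, total_genes: int | None = None) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    flags = df.set_index(df.columns[0]).astype(bool)
    flags.index.name = "gene_id"
    return PhenotypeMatrix(flags=flags, total_genes=total_genes or len(flags))
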