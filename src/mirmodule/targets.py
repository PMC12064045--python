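"""Seed-family x gene target-site count matrix and module gene selection.

The matrix counts predicted canonical seed sites of each enriched seed
family in each expressed gene's 3'UTR.  Genes are retained only when
expressed above ``gene_min_rpm`` (mean reads per million) in at least one
of the two focal conditions, mirroring how the matrix is built before any
thresholding.  A gene belongs to the *module target set* when its
cumulative site count over all families reaches ``site_threshold`` --
the redundancy criterion that separates repeatedly targeted
differentiation/temporal genes from stem-cell identity genes with zero
or one site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import PredictionRecord, SiteMatch

__all__ = [
    "MatrixConfig",
    "TargetSiteMatrix",
    "build_site_matrix",
    "matrix_from_scan",
    "total_sites",
    "select_module_genes",
    "interactome_edges",
]


@dataclass(frozen=True)
class MatrixConfig:
    """Expression filter and site threshold of the target matrix stage."""

    gene_min_rpm: float = 100.0
    site_threshold: int = 5

    def __post_init__(self) -> None:
        if self.site_threshold < 1:
            raise ValueError("site_threshold must be >= 1")
        if self.gene_min_rpm < 0:
            raise ValueError("gene_min_rpm must be >= 0")


@dataclass
class TargetSiteMatrix:
    """Non-negative integer site counts, families as rows, genes as columns."""

    counts: pd.DataFrame
    provenance: str = "scanned"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("family and gene identifiers must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("site counts must be non-negative")
        if self.provenance not in ("scanned", "imported"):
            raise ValueError("provenance must be 'scanned' or 'imported'")
        self.counts = self.counts.astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        # genes as rows for interchange, families as columns
        self.counts.T.to_csv(path, sep="\t", index_label="gene")


def build_site_matrix(
    families: Sequence[str],
    records: Iterable[PredictionRecord] | Mapping[str, Iterable[SiteMatch]],
    gene_expression: pd.DataFrame | None = None,
    config: MatrixConfig | None = None,
    focal_conditions: Sequence[str] = ("nab", "elav"),
    provenance: str = "imported",
    mirna_to_family: Mapping[str, str] | None = None,
) -> TargetSiteMatrix:
    """Assemble the family x gene site-count matrix.

    Parameters
    ----------
    families
        seed-family row identifiers; records naming a family absent from
        this list raise an error (seed-sharing miRNAs must be collapsed
        to one family row before counting -- pass ``mirna_to_family`` to
        map per-miRNA records onto family rows).
    records
        either an iterable of :class:`PredictionRecord` or a mapping
        family -> iterable of sites.
    gene_expression
        gene x condition mean reads-per-million table; genes not above
        ``config.gene_min_rpm`` in at least one focal condition are
        dropped, as are genes targeted by no family.
    """
    config = config or MatrixConfig()
    if not families:
        raise ValueError("families must be non-empty")
    family_set = set(families)
    mirna_to_family = dict(mirna_to_family or {})

    cells: dict[tuple[str, str], int] = {}

    def add(family: str, gene: str, count: int) -> None:
        family = mirna_to_family.get(family, family)
        if family not in family_set:
            raise ValueError(
                f"record references family {family!r} absent from the family list"
            )
        cells[(family, gene)] = cells.get((family, gene), 0) + int(count)

    if isinstance(records, Mapping):
        for family, sites in records.items():
            for site in sites:
                add(family, site.gene, 1)
    else:
        for rec in records:
            add(rec.family_id, rec.gene, rec.site_count)

    genes = sorted({gene for _, gene in cells})
    matrix = pd.DataFrame(0, index=list(families), columns=genes, dtype=int)
    for (family, gene), count in cells.items():
        matrix.loc[family, gene] += count

    if gene_expression is not None:
        focal = [c for c in focal_conditions if c in gene_expression.columns]
        if not focal:
            raise ValueError(
                f"gene expression table lacks focal conditions {focal_conditions}"
            )
        expressed = gene_expression[focal].max(axis=1) > config.gene_min_rpm
        known = [g for g in matrix.columns if g in expressed.index]
        missing = [g for g in matrix.columns if g not in expressed.index]
        if missing:
            raise ValueError(f"genes without expression summaries: {missing[:5]}")
        matrix = matrix[[g for g in known if expressed[g]]]

    # drop genes targeted by no family (all-zero columns)
    matrix = matrix.loc[:, matrix.sum(axis=0) > 0]
    return TargetSiteMatrix(matrix, provenance=provenance)


def matrix_from_scan(
    mirnas,
    utrs: Mapping[str, str],
    gene_expression: pd.DataFrame | None = None,
    config: MatrixConfig | None = None,
    focal_conditions: Sequence[str] = ("nab", "elav"),
) -> TargetSiteMatrix:
    """Scan 3'UTRs with every miRNA and build the family-collapsed matrix.

    Seed-sharing miRNAs contribute to a single family row; because they
    produce identical canonical sites, each family's sites are scanned
    once using one representative member (no double counting).
    """
    from .catalog import apply_families, scan_utr_sites

    mirnas = apply_families(list(mirnas))
    representative: dict[str, object] = {}
    for m in mirnas:
        representative.setdefault(m.family_id, m)
    families = sorted(representative)
    sites: dict[str, list[SiteMatch]] = {f: [] for f in families}
    for family, member in representative.items():
        for gene, utr in utrs.items():
            sites[family].extend(scan_utr_sites(utr, member, gene=gene))
    return build_site_matrix(
        families,
        sites,
        gene_expression=gene_expression,
        config=config,
        focal_conditions=focal_conditions,
        provenance="scanned",
    )


def total_sites(matrix: TargetSiteMatrix) -> pd.Series:
    """Cumulative site count per gene (column sums)."""
    return matrix.counts.sum(axis=0).rename("total_sites")


def select_module_genes(totals: pd.Series, k: int = 5) -> list[str]:
    """Genes with at least ``k`` cumulative sites, by total desc then name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = totals[totals >= k]
    order = sorted(kept.items(), key=lambda item: (-item[1], item[0]))
    return [gene for gene, _ in order]


def interactome_edges(
    matrix: TargetSiteMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Weighted bipartite edges (family, gene, weight=site count > 0)."""
    if genes is None:
        genes = matrix.genes
    unknown = [g for g in genes if g not in matrix.counts.columns]
    if unknown:
        raise ValueError(f"genes absent from matrix: {unknown}")
    rows = [
        {"family": family, "gene": gene, "weight": int(matrix.counts.loc[family, gene])}
        for gene in genes
        for family in matrix.families
        if matrix.counts.loc[family, gene] > 0
    ]
    return pd.DataFrame(rows, columns=["family", "gene", "weight"])
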