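"""End-to-end orchestration: enrich -> families -> matrix -> module ->
promiscuity null -> clustering, with validation, config echo and a
reproducible run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import read_mirna_fasta, read_utr_fasta
from .clustering import cut_clusters, profile_distance, ward_cluster
from .enrichment import AgoEnrichment, EnrichmentConfig, to_cpm
from .io import read_count_table, read_gene_expression
from .module_stats import NullPoolConfig, PromiscuityTest, build_null_pool
from .targets import MatrixConfig, interactome_edges, matrix_from_scan, select_module_genes, total_sites

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "validate_inputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage configurations plus input/output paths.

    The constants mirror the standard analysis: padj < 0.05 with a
    1000-cpm abundance filter for enrichment, a 100-rpm gene expression
    filter, >= 5 cumulative sites for module genes, a 0.1% expression
    share for the null pool, and 3 clusters.
    """

    counts: str = ""
    conditions: str = ""
    mirnas: str = ""
    utrs: str = ""
    gene_expression: str = ""
    outdir: str = "mirmodule_out"
    cond_a: str = "nab"
    cond_b: str = "elav"
    n_clusters: int = 3
    seed: int = 0
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    null: NullPoolConfig = field(default_factory=NullPoolConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key, sub_cls in (
            ("enrichment", EnrichmentConfig),
            ("matrix", MatrixConfig),
            ("null", NullPoolConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub_cls(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> list[tuple[str, str]]:
    """Schema checks; returns (level, message) diagnostics, never raises."""
    diags: list[tuple[str, str]] = []

    def fatal(msg):
        diags.append(("fatal", msg))

    for key in ("counts", "conditions", "mirnas", "utrs", "gene_expression"):
        path = getattr(config, key)
        if not path:
            fatal(f"missing input path: {key}")
        elif not Path(path).exists():
            fatal(f"{key}: file not found: {path}")
    if any(level == "fatal" for level, _ in diags):
        return diags

    try:
        table = read_count_table(config.counts, config.conditions)
    except Exception as exc:  # pragma: no cover - message content varies
        fatal(f"counts: {exc}")
        table = None
    if table is not None:
        for cond in (config.cond_a, config.cond_b):
            if cond not in set(table.conditions.values()):
                fatal(f"counts: condition {cond!r} absent from sample labels")
    try:
        read_mirna_fasta(config.mirnas)
    except Exception as exc:
        fatal(f"mirnas: {exc}")
    try:
        read_utr_fasta(config.utrs)
    except Exception as exc:
        fatal(f"utrs: {exc}")
    try:
        read_gene_expression(config.gene_expression)
    except Exception as exc:
        fatal(f"gene_expression: {exc}")
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write reports under ``config.outdir``.

    Returns a dict with the key result objects.  Any stage failure is
    re-raised as :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    diags = validate_inputs(config)
    fatals = [m for level, m in diags if level == "fatal"]
    if fatals:
        raise StageError("validate", "; ".join(fatals))

    # ---- enrichment -------------------------------------------------------
    try:
        table = read_count_table(config.counts, config.conditions)
        model = AgoEnrichment(table, config.cond_a, config.cond_b, config.enrichment)
        enr = model.fit()
        enriched = enr.select_enriched(direction="up")
        enr.to_tsv(outdir / "enrichment.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("enrichment", str(exc)) from exc
    logger.info("enrichment: %d miRNAs enriched in %s", len(enriched), config.cond_a)

    # ---- families + target matrix ----------------------------------------
    try:
        catalog = read_mirna_fasta(config.mirnas)
        by_name = {m.name: m for m in catalog}
        missing = [m for m in enriched if m not in by_name]
        if missing:
            raise ValueError(f"enriched miRNAs missing from FASTA: {missing}")
        module_mirnas = [by_name[m] for m in enriched]
        utrs = read_utr_fasta(config.utrs)
        expr = read_gene_expression(config.gene_expression)
        matrix = matrix_from_scan(
            module_mirnas,
            utrs,
            gene_expression=expr,
            config=config.matrix,
            focal_conditions=(config.cond_a, config.cond_b),
        )
        matrix.to_tsv(outdir / "site_matrix.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("target_matrix", str(exc)) from exc

    # ---- module genes -----------------------------------------------------
    try:
        totals = total_sites(matrix)
        module_genes = select_module_genes(totals, config.matrix.site_threshold)
        edges = interactome_edges(matrix, module_genes)
        totals.sort_values(ascending=False).to_csv(
            outdir / "gene_totals.tsv", sep="\t"
        )
        edges.to_csv(outdir / "interactome_edges.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("module_genes", str(exc)) from exc
    logger.info("module genes (>= %d sites): %d", config.matrix.site_threshold, len(module_genes))

    # ---- promiscuity vs null ----------------------------------------------
    promiscuity = None
    try:
        if module_genes:
            cpm = to_cpm(table)
            pool = build_null_pool(cpm, config.null, exclude=enriched)
            pool_mirnas = [by_name[m] for m in pool if m in by_name]
            pool_matrix = matrix_from_scan(
                module_mirnas + pool_mirnas, utrs, gene_expression=expr,
                config=config.matrix,
                focal_conditions=(config.cond_a, config.cond_b),
            )
            module_families = sorted({m.family_id for m in module_mirnas})
            test = PromiscuityTest(
                pool_matrix,
                module_families,
                module_genes,
                [m.family_id for m in pool_mirnas],
                config.null,
            )
            promiscuity = test.fit(seed=config.seed)
            (outdir / "promiscuity.json").write_text(
                json.dumps(promiscuity.to_dict(), indent=2)
            )
    except Exception as exc:
        raise StageError("promiscuity", str(exc)) from exc

    # ---- clustering --------------------------------------------------------
    clusters = None
    dendrogram = None
    try:
        if matrix.counts.shape[0] >= 2 and config.n_clusters <= matrix.counts.shape[0]:
            dist = profile_distance(matrix)
            dendrogram = ward_cluster(dist)
            clusters = cut_clusters(dendrogram, config.n_clusters)
            pd.Series(clusters, name="cluster").rename_axis("family").to_csv(
                outdir / "clusters.tsv", sep="\t"
            )
            (outdir / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")
    except Exception as exc:
        raise StageError("clustering", str(exc)) from exc

    # ---- manifest ----------------------------------------------------------
    import numpy, scipy  # versions for the manifest

    manifest = {
        "package": "mirmodule",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_enriched": len(enriched),
        "enriched": enriched,
        "n_module_genes": len(module_genes),
        "module_genes": module_genes,
        "clusters": clusters,
        "empirical_p": promiscuity.empirical_p if promiscuity else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "table": table,
        "enrichment": enr,
        "enriched": enriched,
        "matrix": matrix,
        "totals": totals,
        "module_genes": module_genes,
        "edges": edges,
        "promiscuity": promiscuity,
        "dendrogram": dendrogram,
        "clusters": clusters,
        "manifest": manifest,
    }
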