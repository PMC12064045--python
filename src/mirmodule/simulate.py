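"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators emulate the study design end to end, so every stage is
testable without downloads:

``simulate_mirnas``
    a catalog of mature miRNA sequences in which a planted "module" of
    enriched miRNAs contains shared-seed pairs (defaults: 16 planted
    miRNAs with 3 shared-seed pairs, hence 13 seed families).
``simulate_counts``
    negative-binomial Ago-pulldown counts over multi-condition,
    multi-replicate libraries with per-sample library-size factors and
    condition-specific planted fold changes.
``simulate_transcriptome``
    random 3'UTRs carrying planted canonical seed sites at controlled
    multiplicity: module genes with >= 5 sites, decoy genes straddling
    the site threshold and the expression filter, and background genes
    with Poisson-rate sites.  Backgrounds are rejection-sampled so the
    scanned site count of every gene equals its planted multiplicity --
    planted multiplicities are exact, which makes recovery metrics
    well-defined.

``make_fixture`` bundles everything into one directory (TSV/FASTA/JSON)
plus a machine-readable ground truth.  All randomness flows from the
single user-supplied seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MatureMiRNA, apply_families, scan_utr_sites
from .enrichment import SampleCountTable

__all__ = [
    "SimTruth",
    "simulate_mirnas",
    "simulate_counts",
    "simulate_transcriptome",
    "make_fixture",
]

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))

SITE_TYPE_WEIGHTS = {"8mer": 0.3, "7mer-m8": 0.4, "7mer-A1": 0.3}


@dataclass
class SimTruth:
    """Ground truth and full parameter echo of a simulation."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_mirnas: dict = field(default_factory=dict)  # name -> log2fc
    mirna_families: dict = field(default_factory=dict)  # name -> family_id
    module_genes: dict = field(default_factory=dict)  # gene -> planted site total
    decoy_genes: dict = field(default_factory=dict)  # gene -> planted site total
    background_genes: dict = field(default_factory=dict)  # gene -> planted site total
    gene_above_filter: dict = field(default_factory=dict)  # gene -> bool

    def merge(self, other: "SimTruth") -> "SimTruth":
        merged = SimTruth(self.seed)
        for f in dataclasses.fields(SimTruth):
            if f.name == "seed":
                continue
            mine = getattr(self, f.name)
            theirs = getattr(other, f.name)
            setattr(merged, f.name, {**mine, **theirs})
        return merged

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _random_seq(rng: np.random.Generator, alphabet: np.ndarray, length: int) -> str:
    return "".join(rng.choice(alphabet, size=length))


# ---------------------------------------------------------------------------
# miRNA catalog
# ---------------------------------------------------------------------------

def simulate_mirnas(
    n_mirnas: int = 300,
    n_planted: int = 16,
    n_shared_seed_pairs: int = 3,
    length: int = 21,
    seed: int = 0,
) -> tuple[list[MatureMiRNA], list[str]]:
    """Random mature miRNAs; returns (catalog, planted names).

    The first ``n_planted`` miRNAs are the planted module;
    ``n_shared_seed_pairs`` of them are paired to share a seed (distinct
    full sequences), so the module collapses into
    ``n_planted - n_shared_seed_pairs`` seed families.
    """
    if n_planted > n_mirnas:
        raise ValueError("n_planted cannot exceed n_mirnas")
    if 2 * n_shared_seed_pairs > n_planted:
        raise ValueError("too many shared-seed pairs for the planted set")
    rng = np.random.default_rng(seed)
    width = len(str(n_mirnas))
    names = [f"miR-sim-{i + 1:0{width}d}" for i in range(n_mirnas)]
    seeds_used: set[str] = set()
    mirnas: list[MatureMiRNA] = []
    share_with: dict[int, int] = {}  # planted index -> partner index
    for pair in range(n_shared_seed_pairs):
        share_with[2 * pair + 1] = 2 * pair
    for i, name in enumerate(names):
        partner = share_with.get(i)
        while True:
            seq = _random_seq(rng, _RNA, length)
            if partner is not None:
                # same seed as the partner, different 3' half
                seq = mirnas[partner].sequence[:8] + seq[8:]
                if seq != mirnas[partner].sequence:
                    break
            elif seq[1:8] not in seeds_used:
                break
        seeds_used.add(seq[1:8])
        mirnas.append(MatureMiRNA(name, seq))
    return apply_families(mirnas), names[:n_planted]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    mirna_names: Sequence[str] | None = None,
    n_mirnas: int = 300,
    conditions: Sequence[str] = ("nab", "elav", "repo"),
    replicates: int = 3,
    base_mean_log: tuple[float, float] = (np.log(100.0), 1.5),
    dispersion: float = 0.05,
    planted: Mapping[str, float] | Sequence[str] | None = None,
    n_planted: int = 16,
    log2fc_range: tuple[float, float] = (1.5, 3.0),
    planted_base_range: tuple[float, float] = (1000.0, 4000.0),
    focal_condition: str = "nab",
    library_size_sigma: float = 0.15,
    seed: int = 0,
) -> tuple[SampleCountTable, SimTruth]:
    """NB counts with condition-specific planted fold changes.

    Planted miRNAs get base means from ``planted_base_range`` and a
    ``2**log2fc`` multiplier in the focal condition; all other miRNAs
    share one mean across conditions drawn from a lognormal
    (``base_mean_log`` = (mu, sigma) on the natural-log scale).
    Per-sample library-size factors are lognormal.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if mirna_names is None:
        width = len(str(n_mirnas))
        mirna_names = [f"miR-sim-{i + 1:0{width}d}" for i in range(n_mirnas)]
    mirna_names = list(mirna_names)
    n = len(mirna_names)

    if planted is None:
        planted = mirna_names[:n_planted]
    if not isinstance(planted, Mapping):
        lo, hi = log2fc_range
        planted = {name: float(rng.uniform(lo, hi)) for name in planted}
    unknown = [m for m in planted if m not in set(mirna_names)]
    if unknown:
        raise ValueError(f"planted miRNAs absent from catalog: {unknown}")
    if planted and focal_condition not in conditions:
        raise ValueError(f"focal condition {focal_condition!r} not in conditions")

    base = np.exp(rng.normal(base_mean_log[0], base_mean_log[1], size=n))
    planted_idx = {name: mirna_names.index(name) for name in planted}
    for name, idx in planted_idx.items():
        base[idx] = rng.uniform(*planted_base_range)

    sample_names: list[str] = []
    cond_map: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for cond in conditions:
        mu_cond = base.copy()
        if cond == focal_condition:
            for name, idx in planted_idx.items():
                mu_cond[idx] = base[idx] * 2.0 ** planted[name]
        for rep in range(1, replicates + 1):
            sample = f"{cond}_{rep}"
            sample_names.append(sample)
            cond_map[sample] = cond
            size_factor = float(np.exp(rng.normal(0.0, library_size_sigma)))
            columns.append(_nb_draw(rng, mu_cond * size_factor, dispersion))

    counts = pd.DataFrame(
        np.column_stack(columns), index=mirna_names, columns=sample_names
    ).rename_axis("mirna")
    table = SampleCountTable(counts, cond_map)
    truth = SimTruth(
        seed=seed,
        params={
            "n_mirnas": n,
            "conditions": list(conditions),
            "replicates": replicates,
            "base_mean_log": list(base_mean_log),
            "dispersion": dispersion,
            "log2fc_range": list(log2fc_range),
            "planted_base_range": list(planted_base_range),
            "focal_condition": focal_condition,
            "library_size_sigma": library_size_sigma,
        },
        planted_mirnas=dict(planted),
    )
    return table, truth


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _plant_gene(
    rng: np.random.Generator,
    length: int,
    site_strings: Sequence[str],
    family_reps: Sequence[MatureMiRNA],
    planted_per_family: Mapping[str, int],
    max_attempts: int = 50,
) -> str:
    """Random UTR with the given sites inserted, rejection-sampled so the
    scanner recovers exactly the planted per-family counts."""
    if length < 30:
        raise ValueError("UTR length must be >= 30")
    for _ in range(max_attempts):
        background = _random_seq(rng, _DNA, length)
        anchors = np.sort(rng.integers(0, length + 1, size=len(site_strings)))
        pieces = []
        prev = 0
        for anchor, site in zip(anchors, site_strings):
            pieces.append(background[prev:anchor])
            pieces.append(site)
            prev = anchor
        pieces.append(background[prev:])
        utr = "".join(pieces)
        scanned = {
            rep.family_id: len(scan_utr_sites(utr, rep)) for rep in family_reps
        }
        if all(
            scanned.get(fam, 0) == planted_per_family.get(fam, 0)
            for fam in set(scanned) | set(planted_per_family)
        ):
            return utr
    raise RuntimeError(
        f"could not realize planted site multiplicities in a {length}-nt UTR "
        f"after {max_attempts} attempts"
    )


def _draw_sites(
    rng: np.random.Generator, family_reps: Sequence[MatureMiRNA], total: int
) -> tuple[list[str], dict[str, int]]:
    """Pick ``total`` sites spread over the families; returns site strings
    and per-family counts."""
    types = list(SITE_TYPE_WEIGHTS)
    weights = np.array([SITE_TYPE_WEIGHTS[t] for t in types])
    weights = weights / weights.sum()
    strings: list[str] = []
    per_family: dict[str, int] = {}
    for _ in range(total):
        rep = family_reps[rng.integers(len(family_reps))]
        site_type = types[rng.choice(len(types), p=weights)]
        strings.append(rep.site_string(site_type))
        per_family[rep.family_id] = per_family.get(rep.family_id, 0) + 1
    return strings, per_family


def simulate_transcriptome(
    module_mirnas: Sequence[MatureMiRNA],
    n_module_genes: int = 12,
    decoy_sites_above: Sequence[int] = (1, 2, 3, 4),
    decoy_sites_below: Sequence[int] = (5, 6),
    n_background_genes: int = 44,
    module_sites_range: tuple[int, int] = (5, 15),
    background_site_rate: float = 0.5,
    utr_length_range: tuple[int, int] = (150, 450),
    decoy_utr_length: int = 100,
    expression_conditions: Sequence[str] = ("nab", "elav"),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, SimTruth]:
    """Random 3'UTRs with planted canonical sites plus an expression table.

    Gene classes:

    * ``modgene``: planted total uniform in ``module_sites_range``
      (>= the site threshold), expressed well above the 100-rpm filter.
    * ``decoyA``: 1-4 planted sites, expressed above the filter --
      exercises the k = 5 boundary from below.
    * ``decoyB``: >= 5 planted sites but expressed *below* the filter --
      exercises the expression filter's precedence over the threshold.
    * ``bg``: Poisson(``background_site_rate``) planted sites; half
      above, half below the expression filter.

    Returns (utrs, gene_expression table in reads per million, truth).
    """
    if not module_mirnas:
        raise ValueError("module_mirnas must be non-empty")
    rng = np.random.default_rng(seed)
    reps: dict[str, MatureMiRNA] = {}
    for m in module_mirnas:
        reps.setdefault(m.family_id, m)
    family_reps = list(reps.values())

    utrs: dict[str, str] = {}
    expression: dict[str, dict[str, float]] = {}
    truth = SimTruth(
        seed=seed,
        params={
            "n_module_genes": n_module_genes,
            "decoy_sites_above": list(decoy_sites_above),
            "decoy_sites_below": list(decoy_sites_below),
            "n_background_genes": n_background_genes,
            "module_sites_range": list(module_sites_range),
            "background_site_rate": background_site_rate,
            "utr_length_range": list(utr_length_range),
            "decoy_utr_length": decoy_utr_length,
        },
        mirna_families={m.name: m.family_id for m in module_mirnas},
    )

    def rpm_row(above: bool) -> dict[str, float]:
        if above:
            values = rng.uniform(150.0, 1000.0, size=len(expression_conditions))
        else:
            values = rng.uniform(5.0, 90.0, size=len(expression_conditions))
        return dict(zip(expression_conditions, np.round(values, 2)))

    def add_gene(name, length, total, above, bucket):
        strings, per_family = _draw_sites(rng, family_reps, total)
        utrs[name] = _plant_gene(rng, length, strings, family_reps, per_family)
        expression[name] = rpm_row(above)
        bucket[name] = total
        truth.gene_above_filter[name] = bool(above)

    lo, hi = module_sites_range
    for i in range(n_module_genes):
        total = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(*utr_length_range))
        add_gene(f"modgene{i + 1:02d}", length, total, True, truth.module_genes)
    for i, total in enumerate(decoy_sites_above):
        add_gene(f"decoyA{i + 1:02d}", decoy_utr_length, int(total), True, truth.decoy_genes)
    for i, total in enumerate(decoy_sites_below):
        add_gene(f"decoyB{i + 1:02d}", decoy_utr_length, int(total), False, truth.decoy_genes)
    half = n_background_genes // 2
    for i in range(n_background_genes):
        total = int(rng.poisson(background_site_rate))
        length = int(rng.integers(*utr_length_range))
        add_gene(f"bg{i + 1:03d}", length, total, i < half, truth.background_genes)

    expr_df = (
        pd.DataFrame.from_dict(expression, orient="index")
        .rename_axis("gene")
        .loc[list(utrs)]
    )
    return utrs, expr_df, truth


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def make_fixture(outdir: str | Path, seed: int = 0, **overrides) -> dict:
    """Generate a complete pipeline input bundle under ``outdir``.

    Writes ``counts.tsv``, ``conditions.tsv``, ``mirnas.fasta``,
    ``utrs.fasta``, ``gene_expression.tsv`` and ``truth.json``; returns a
    dict of the paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(seed).generate_state(3) % (2**31)

    mirnas, planted_names = simulate_mirnas(
        n_mirnas=overrides.get("n_mirnas", 300), seed=int(child[0])
    )
    table, truth_counts = simulate_counts(
        mirna_names=[m.name for m in mirnas],
        planted=planted_names,
        dispersion=overrides.get("dispersion", 0.05),
        seed=int(child[1]),
    )
    planted_mirnas = [m for m in mirnas if m.name in set(planted_names)]
    utrs, expr, truth_tx = simulate_transcriptome(
        planted_mirnas, seed=int(child[2])
    )
    truth = truth_counts.merge(truth_tx)
    truth.seed = seed
    truth.mirna_families = {m.name: m.family_id for m in mirnas}

    paths = {
        "counts": outdir / "counts.tsv",
        "conditions": outdir / "conditions.tsv",
        "mirnas": outdir / "mirnas.fasta",
        "utrs": outdir / "utrs.fasta",
        "gene_expression": outdir / "gene_expression.tsv",
        "truth": outdir / "truth.json",
    }
    table.counts.to_csv(paths["counts"], sep="\t", index_label="mirna")
    pd.Series(table.conditions, name="condition").rename_axis("sample").to_csv(
        paths["conditions"], sep="\t"
    )
    with open(paths["mirnas"], "w") as fh:
        for m in mirnas:
            fh.write(f">{m.name}\n{m.sequence}\n")
    with open(paths["utrs"], "w") as fh:
        for gene, utr in utrs.items():
            fh.write(f">{gene}\n{utr}\n")
    expr.to_csv(paths["gene_expression"], sep="\t")
    truth.to_json(paths["truth"])

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "mirnas": mirnas,
        "planted_names": planted_names,
        "table": table,
        "utrs": utrs,
        "gene_expression": expr,
        "truth": truth,
    }
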