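"""Differential enrichment of Ago-bound miRNA counts between cell types.

The data are small-RNA-seq counts from Argonaute pulldowns performed in
distinct cell populations (e.g. neural stem cells, neurons, glia), three
replicates per condition plus an un-pulled input.  The model is the
standard negative-binomial (NB) count model for bulk RNA counts:

    K_ij ~ NB(mean = s_j * q_ij,  Var = mu + alpha_i * mu^2)

with per-sample size factors s_j (median-of-ratios), a per-miRNA
dispersion alpha_i estimated by method of moments and shrunk toward a
fitted mean-dispersion trend, and a Wald test on the log2 fold change of
condition means.  p-values are Benjamini-Hochberg adjusted.

The entry point is the model/results pair::

    res = AgoEnrichment(table, "nab", "elav").fit()
    res.summary()
    res.select_enriched(direction="up")

Enrichment calls combine three filters: adjusted p below ``padj_max``,
fold-change sign, and a minimum abundance (counts per million) in at
least one sample of the focal condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleCountTable",
    "EnrichmentConfig",
    "AgoEnrichment",
    "EnrichmentResults",
    "compute_size_factors",
    "to_cpm",
    "relative_to_mean",
    "estimate_dispersion",
    "test_differential",
    "bh_adjust",
    "select_enriched",
    "pca_samples",
]


@dataclass
class SampleCountTable:
    """miRNA x sample integer counts with per-sample condition labels."""

    counts: pd.DataFrame
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA identifiers: {dupes}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        self.conditions = {s: self.conditions[s] for s in counts.columns}

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions.values():
            if c not in seen:
                seen.append(c)
        return seen

    def replicate_index(self) -> dict[str, int]:
        """1-based replicate number of each sample within its condition."""
        counter: dict[str, int] = {}
        out: dict[str, int] = {}
        for sample, cond in self.conditions.items():
            counter[cond] = counter.get(cond, 0) + 1
            out[sample] = counter[cond]
        return out


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds and numerical settings of the enrichment stage.

    padj_max
        BH-adjusted significance cutoff (0.05).
    min_cpm
        abundance filter: required counts-per-million in at least one
        sample of the focal condition (1000 reads per million).
    pseudocount
        added symmetrically to both condition means (normalized-count
        units) before the log2 ratio, so equal means give exactly 0 and
        zero counts stay finite.
    trend_shrinkage
        weight of the fitted mean-dispersion trend in the final
        dispersion (0 = raw method-of-moments, 1 = pure trend).
    """

    padj_max: float = 0.05
    min_cpm: float = 1000.0
    pseudocount: float = 0.5
    trend_shrinkage: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.padj_max < 1.0:
            raise ValueError("padj_max must lie in (0, 1)")
        if self.min_cpm <= 0 or self.pseudocount <= 0:
            raise ValueError("min_cpm and pseudocount must be strictly positive")
        if not 0.0 <= self.trend_shrinkage <= 1.0:
            raise ValueError("trend_shrinkage must lie in [0, 1]")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_size_factors(table: SampleCountTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    factor_j = median over miRNAs i with positive geometric mean of
    count_ij / geomean_i(counts).
    """
    counts = table.counts if isinstance(table, SampleCountTable) else table
    arr = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(arr.sum(axis=0) == 0)].tolist()
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    with np.errstate(divide="ignore"):
        log_geomean = np.log(arr).mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no miRNA has nonzero counts in every sample; "
            "cannot compute median-of-ratios factors"
        )
    ratios = arr[usable] / np.exp(log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        bad = counts.columns[factors <= 0].tolist()
        raise ValueError(f"non-positive size factor for samples: {bad}")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(table: SampleCountTable) -> pd.DataFrame:
    return table.counts / compute_size_factors(table)


def to_cpm(table: SampleCountTable | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each sample column rescaled to sum to 1e6."""
    counts = table.counts if isinstance(table, SampleCountTable) else table
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return counts / totals * 1e6


def relative_to_mean(normalized: pd.DataFrame) -> pd.DataFrame:
    """Scale each row by its mean across samples (heat-map normalization).

    Rows whose mean is zero cannot be scaled and are dropped with a warning.
    """
    means = normalized.mean(axis=1)
    zero = means == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero rows before per-row scaling",
            stacklevel=2,
        )
    kept = normalized.loc[~zero]
    return kept.div(means[~zero], axis=0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    table: SampleCountTable,
    conditions: Sequence[str] | None = None,
    trend_shrinkage: float = 0.3,
) -> pd.Series:
    """Per-miRNA NB dispersion alpha >= 0 on normalized counts.

    Method of moments within each condition with >= 2 replicates,
    alpha = max(0, (s^2 - mu) / mu^2), combined across conditions with
    weights (n_c - 1), then shrunk toward a fitted trend
    alpha(mu) = a0 + a1/mu by a weighted average.
    """
    if conditions is None:
        conditions = table.condition_labels()
    norm = normalized_counts(table)
    groups = [
        norm[table.samples_of(c)] for c in conditions if len(table.samples_of(c)) >= 2
    ]
    if not groups:
        raise ValueError(
            "no condition has >= 2 replicates; pass a fixed dispersion instead "
            "(e.g. EnrichmentConfig with a user-supplied alpha)"
        )
    num = pd.Series(0.0, index=norm.index)
    den = 0.0
    mu_all = pd.Series(0.0, index=norm.index)
    n_samples = 0
    for g in groups:
        n = g.shape[1]
        mu = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (s2 - mu) / mu.pow(2)
        alpha = alpha.replace([np.inf, -np.inf], np.nan).fillna(0.0).clip(lower=0.0)
        num += alpha * (n - 1)
        den += n - 1
        mu_all += mu * n
        n_samples += n
    alpha_mom = num / den
    mu_mean = mu_all / n_samples

    alpha_trend = _fit_dispersion_trend(mu_mean, alpha_mom)
    w = trend_shrinkage
    shrunk = (1.0 - w) * alpha_mom + w * alpha_trend
    return shrunk.clip(lower=0.0).rename("dispersion")


def _fit_dispersion_trend(mu: pd.Series, alpha: pd.Series) -> pd.Series:
    """Least-squares fit of alpha ~ a0 + a1/mu over miRNAs with mu > 0."""
    ok = mu > 0
    if ok.sum() < 3:
        const = float(alpha[ok].median()) if ok.any() else 0.0
        return pd.Series(const, index=mu.index)
    x = 1.0 / mu[ok].to_numpy()
    y = alpha[ok].to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    with np.errstate(divide="ignore"):
        fitted = coef[0] + coef[1] / mu.to_numpy()
    fitted = np.where(mu.to_numpy() > 0, fitted, 0.0)
    return pd.Series(np.clip(fitted, 0.0, None), index=mu.index)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_differential(
    table: SampleCountTable,
    cond_a: str,
    cond_b: str,
    config: EnrichmentConfig | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of cond_a over cond_b for every miRNA.

    Returns a DataFrame indexed by miRNA with columns
    ``mean_cpm_<cond>`` (for every condition in the table), ``base_mean_a``,
    ``base_mean_b`` (normalized counts), ``log2fc``, ``se``, ``stat``,
    ``pvalue``, ``padj``, sorted by (padj, -|log2fc|, name).
    """
    config = config or EnrichmentConfig()
    samples_a = table.samples_of(cond_a)
    samples_b = table.samples_of(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both conditions need >= 2 replicates; got "
            f"{cond_a}: {len(samples_a)}, {cond_b}: {len(samples_b)}"
        )
    if dispersion is None:
        dispersion = estimate_dispersion(
            table, (cond_a, cond_b), trend_shrinkage=config.trend_shrinkage
        )
    norm = normalized_counts(table)
    cpm = to_cpm(table)

    mu_a = norm[samples_a].mean(axis=1)
    mu_b = norm[samples_b].mean(axis=1)
    pc = config.pseudocount
    log2fc = np.log2((mu_a + pc) / (mu_b + pc))

    alpha = dispersion.reindex(norm.index).to_numpy()
    n_a, n_b = len(samples_a), len(samples_b)
    # delta method on log(mu): Var(log mu_hat) ~ Var(mu_hat) / mu^2
    var_a = (mu_a + pc + alpha * (mu_a + pc) ** 2) / (n_a * (mu_a + pc) ** 2)
    var_b = (mu_b + pc + alpha * (mu_b + pc) ** 2) / (n_b * (mu_b + pc) ** 2)
    se = np.sqrt(var_a + var_b) / np.log(2)
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = bh_adjust(pvalue)

    records = pd.DataFrame(
        {
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        }
    )
    for cond in table.condition_labels():
        records[f"mean_cpm_{cond}"] = cpm[table.samples_of(cond)].mean(axis=1)
    records = records.rename_axis("mirna")
    records["abs_log2fc"] = records["log2fc"].abs()
    records = records.sort_values(
        ["padj", "abs_log2fc", "mirna"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns="abs_log2fc")
    return records


# not a test, despite the conventional name
test_differential.__test__ = False  # type: ignore[attr-defined]


def select_enriched(
    records: pd.DataFrame,
    table: SampleCountTable,
    focal_condition: str,
    config: EnrichmentConfig | None = None,
    direction: str = "up",
) -> list[str]:
    """miRNAs passing significance, fold-change sign and abundance filters.

    ``direction="up"`` keeps log2fc > 0 (enriched in the test's condition A),
    ``"down"`` keeps log2fc < 0.  The abundance filter requires
    ``min_cpm`` counts per million in at least one sample of
    ``focal_condition``.
    """
    config = config or EnrichmentConfig()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    cpm = to_cpm(table)
    focal = cpm[table.samples_of(focal_condition)]
    max_cpm = focal.max(axis=1)
    keep = records["padj"] < config.padj_max
    keep &= records["log2fc"] > 0 if direction == "up" else records["log2fc"] < 0
    keep &= max_cpm.reindex(records.index) >= config.min_cpm
    return records.index[keep].tolist()


# ---------------------------------------------------------------------------
# sample-level summaries
# ---------------------------------------------------------------------------

def pca_samples(
    normalized: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(x+1)-transformed, per-miRNA-centered data.

    Returns (coordinates: sample x component DataFrame, variance fractions).
    """
    n_samples = normalized.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(normalized.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)={min(normalized.shape)}"
        )
    x = np.log2(normalized.to_numpy(dtype=float).T + 1.0)  # samples x miRNAs
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    coords_df = pd.DataFrame(
        coords,
        index=normalized.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords_df, frac


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class AgoEnrichment:
    """NB Wald differential-enrichment model for one condition contrast.

    Parameters
    ----------
    table
        counts with condition labels.
    cond_a, cond_b
        contrast: log2 fold changes are cond_a over cond_b, so miRNAs
        higher in ``cond_a`` have positive log2fc.
    config
        thresholds; defaults follow the standard analysis (padj < 0.05,
        1000 cpm abundance filter).
    """

    def __init__(
        self,
        table: SampleCountTable,
        cond_a: str,
        cond_b: str,
        config: EnrichmentConfig | None = None,
    ):
        labels = set(table.conditions.values())
        for cond in (cond_a, cond_b):
            if cond not in labels:
                raise ValueError(f"condition {cond!r} not present in table")
        self.table = table
        self.cond_a = cond_a
        self.cond_b = cond_b
        self.config = config or EnrichmentConfig()

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        conditions: Mapping[str, str],
        cond_a: str,
        cond_b: str,
        config: EnrichmentConfig | None = None,
    ) -> "AgoEnrichment":
        return cls(SampleCountTable(counts, conditions), cond_a, cond_b, config)

    def fit(self) -> "EnrichmentResults":
        dispersion = estimate_dispersion(
            self.table,
            (self.cond_a, self.cond_b),
            trend_shrinkage=self.config.trend_shrinkage,
        )
        records = test_differential(
            self.table, self.cond_a, self.cond_b, self.config, dispersion
        )
        return EnrichmentResults(self, records, dispersion)


@dataclass
class EnrichmentResults:
    """Fitted differential-enrichment results."""

    model: AgoEnrichment
    records: pd.DataFrame
    dispersion: pd.Series
    size_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.size_factors is None:
            self.size_factors = compute_size_factors(self.model.table)

    @property
    def config(self) -> EnrichmentConfig:
        return self.model.config

    def select_enriched(
        self, direction: str = "up", focal_condition: str | None = None
    ) -> list[str]:
        focal = focal_condition or (
            self.model.cond_a if direction == "up" else self.model.cond_b
        )
        return select_enriched(
            self.records, self.model.table, focal, self.config, direction
        )

    def summary(self, top: int = 20) -> str:
        m = self.model
        n_sig = int((self.records["padj"] < self.config.padj_max).sum())
        enriched = self.select_enriched("up")
        lines = [
            "NB Wald differential enrichment",
            "=" * 60,
            f"contrast:      {m.cond_a} vs {m.cond_b}",
            f"miRNAs tested: {len(self.records)}",
            f"samples:       {len(m.table.samples_of(m.cond_a))} vs "
            f"{len(m.table.samples_of(m.cond_b))}",
            f"padj < {self.config.padj_max:g}: {n_sig}",
            f"enriched in {m.cond_a} (padj, sign, >= {self.config.min_cpm:g} cpm): "
            f"{len(enriched)}",
            "-" * 60,
        ]
        cols = ["log2fc", "se", "pvalue", "padj"]
        lines.append(self.records[cols].head(top).to_string(float_format="%.3g"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index_label="mirna")
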