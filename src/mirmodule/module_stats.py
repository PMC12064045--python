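"""Promiscuity of a miRNA set toward a focal gene set, with a Monte-Carlo null.

The *promiscuity score* of a miRNA (or seed family) is its total number
of predicted sites over a fixed focal gene set -- here the iconic
differentiation and temporal-patterning genes.  A candidate module's
mean score per member is compared against sets of the same size drawn
from a pool of miRNAs that are essentially not expressed in the tissue
(maximal expression share across samples below ``low_expr_frac``,
default 0.1% of total miRNA reads).  The add-one empirical upper-tail
p-value over ``n_draws`` random sets quantifies whether the module is
more promiscuous toward the focal genes than chance combinations.

Means are reported with the standard error of the mean (SEM), matching
the mean +- SEM convention of the source data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NullPoolConfig",
    "promiscuity_score",
    "build_null_pool",
    "null_distribution",
    "NullDistribution",
    "PromiscuityTest",
    "PromiscuityResults",
]


@dataclass(frozen=True)
class NullPoolConfig:
    """Configuration of the low-expression null pool and Monte-Carlo draw."""

    low_expr_frac: float = 0.001
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_expr_frac < 1.0:
            raise ValueError("low_expr_frac must lie in (0, 1)")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


def _as_counts(matrix) -> pd.DataFrame:
    counts = getattr(matrix, "counts", matrix)
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("expected a TargetSiteMatrix or a DataFrame of site counts")
    return counts


def promiscuity_score(
    matrix, members: Sequence[str], focal_genes: Sequence[str]
) -> tuple[pd.Series, float, float]:
    """Per-member site totals over the focal genes, with mean and SEM.

    Members without a row in the matrix contribute zero sites (a miRNA
    with no predicted sites anywhere is a legitimate set member).
    """
    counts = _as_counts(matrix)
    if len(members) == 0:
        raise ValueError("miRNA set must be non-empty")
    if len(focal_genes) == 0:
        raise ValueError("focal gene set must be non-empty")
    genes = [g for g in focal_genes if g in counts.columns]
    sub = counts.reindex(index=list(members), columns=genes).fillna(0)
    totals = sub.sum(axis=1).astype(float).rename("total_sites")
    mean = float(totals.mean())
    if len(totals) > 1:
        sem = float(totals.std(ddof=1) / np.sqrt(len(totals)))
    else:
        sem = 0.0
    return totals, mean, sem


def build_null_pool(
    expression: pd.DataFrame,
    config: NullPoolConfig | None = None,
    exclude: Sequence[str] = (),
) -> list[str]:
    """miRNAs whose maximal expression share across samples is below cutoff.

    ``expression`` is a miRNA x sample table of non-negative abundances
    (raw counts or cpm; shares are computed per sample column).
    """
    config = config or NullPoolConfig()
    totals = expression.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total expression: {bad}")
    shares = expression / totals
    max_share = shares.max(axis=1)
    pool = [
        m
        for m in expression.index[max_share < config.low_expr_frac]
        if m not in set(exclude)
    ]
    if not pool:
        raise ValueError(
            "low-expression pool is empty; raise low_expr_frac to admit miRNAs"
        )
    return pool


@dataclass
class NullDistribution:
    """Null means from random same-size miRNA sets, and the empirical p."""

    null_means: np.ndarray
    observed_mean: float
    n_draws: int
    seed: int

    @property
    def empirical_p(self) -> float:
        """Add-one upper-tail p: (1 + #{null >= observed}) / (1 + n_draws)."""
        exceed = int(np.sum(self.null_means >= self.observed_mean))
        return (1 + exceed) / (1 + self.n_draws)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.null_means, q))


def null_distribution(
    pool: Sequence[str],
    set_size: int,
    matrix,
    focal_genes: Sequence[str],
    observed_mean: float,
    n_draws: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Monte-Carlo null of mean promiscuity for random size-matched sets.

    Each draw samples ``set_size`` miRNAs without replacement from the
    pool and records the mean site total over the focal genes.  Fully
    reproducible from ``seed``.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if len(pool) < set_size:
        raise ValueError(
            f"pool of size {len(pool)} cannot supply sets of size {set_size}"
        )
    counts = _as_counts(matrix)
    genes = [g for g in focal_genes if g in counts.columns]
    sub = counts.reindex(index=list(pool), columns=genes).fillna(0)
    per_mirna = sub.sum(axis=1).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pool_idx = np.arange(len(pool))
    means = np.empty(n_draws)
    for d in range(n_draws):
        take = rng.choice(pool_idx, size=set_size, replace=False)
        means[d] = per_mirna[take].mean()
    return NullDistribution(means, float(observed_mean), n_draws, seed)


class PromiscuityTest:
    """Model comparing a miRNA set's promiscuity against a randomized null.

    Parameters
    ----------
    matrix
        family/miRNA x gene site-count matrix (rows must cover pool members;
        missing rows count as zero sites).
    module
        the candidate module (miRNA or family names).
    focal_genes
        focal gene set (e.g. iconic differentiation + temporal genes).
    pool
        low-expression miRNAs from :func:`build_null_pool`.
    """

    def __init__(
        self,
        matrix,
        module: Sequence[str],
        focal_genes: Sequence[str],
        pool: Sequence[str],
        config: NullPoolConfig | None = None,
    ):
        self.matrix = matrix
        self.module = list(module)
        self.focal_genes = list(focal_genes)
        self.pool = list(pool)
        self.config = config or NullPoolConfig()

    def fit(
        self, n_draws: int | None = None, seed: int | None = None
    ) -> "PromiscuityResults":
        n_draws = self.config.n_draws if n_draws is None else n_draws
        seed = self.config.seed if seed is None else seed
        totals, mean, sem = promiscuity_score(self.matrix, self.module, self.focal_genes)
        null = null_distribution(
            self.pool,
            len(self.module),
            self.matrix,
            self.focal_genes,
            mean,
            n_draws=n_draws,
            seed=seed,
        )
        return PromiscuityResults(self, totals, mean, sem, null)


@dataclass
class PromiscuityResults:
    model: PromiscuityTest
    per_mirna_totals: pd.Series
    mean: float
    sem: float
    null: NullDistribution

    @property
    def empirical_p(self) -> float:
        return self.null.empirical_p

    def summary(self) -> str:
        n = self.null
        lines = [
            "Module promiscuity vs randomized null",
            "=" * 60,
            f"module size:        {len(self.model.module)}",
            f"focal genes:        {len(self.model.focal_genes)}",
            f"mean +- SEM:        {self.mean:.2f} +- {self.sem:.2f} sites/miRNA",
            f"null pool size:     {len(self.model.pool)}",
            f"null draws (seed):  {n.n_draws} ({n.seed})",
            f"null mean (median): {n.null_means.mean():.2f} ({np.median(n.null_means):.2f})",
            f"null 95th pct:      {n.percentile(95):.2f}",
            f"empirical p:        {self.empirical_p:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "module": self.model.module,
            "focal_genes": self.model.focal_genes,
            "per_mirna_totals": self.per_mirna_totals.to_dict(),
            "mean": self.mean,
            "sem": self.sem,
            "null": {
                "n_draws": self.null.n_draws,
                "seed": self.null.seed,
                "mean": float(self.null.null_means.mean()),
                "percentiles": {
                    str(q): self.null.percentile(q) for q in (5, 25, 50, 75, 95)
                },
            },
            "empirical_p": self.empirical_p,
        }
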