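"""Readers for the pipeline's tabular inputs.

All TSV readers tolerate CRLF line endings and ``#`` comment lines.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import SampleCountTable

__all__ = [
    "read_counts",
    "read_conditions",
    "read_count_table",
    "read_gene_expression",
]


def read_counts(path: str | Path) -> pd.DataFrame:
    """miRNA x sample counts; first column is the miRNA identifier.

    Raw integer counts are expected.  If the table holds non-integer
    values it is accepted as already normalized, with a warning
    (median-of-ratios re-normalization of such a table is a no-op to
    first order).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df = df.rename_axis("mirna")
    if df.empty:
        raise ValueError(f"{path}: no count rows found")
    values = df.to_numpy()
    if (values < 0).any():
        raise ValueError(f"{path}: negative counts")
    if not (values == values.astype(int)).all():
        warnings.warn(
            f"{path}: non-integer values; treating the table as already "
            "normalized counts",
            stacklevel=2,
        )
    return df


def read_conditions(path: str | Path) -> dict[str, str]:
    """sample -> condition map from a two-column TSV or a YAML mapping."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a sample -> condition mapping")
        return {str(k): str(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need columns (sample, condition)")
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def read_count_table(
    counts_path: str | Path, conditions_path: str | Path
) -> SampleCountTable:
    counts = read_counts(counts_path)
    conditions = read_conditions(conditions_path)
    return SampleCountTable(counts, conditions)


def read_gene_expression(path: str | Path) -> pd.DataFrame:
    """gene x condition mean reads-per-million table."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0).rename_axis("gene")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df
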