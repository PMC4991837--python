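"""Summaries of an RPKM expression matrix (genes x tissues).

The matrix is carried as a pandas DataFrame with gene ids on the index and
tissue labels on the columns. Conventions follow the field's usual survey
style: the baseline tissue is the one with the lowest mean expression; a
gene is "expressed" when it reaches the threshold (default 50 RPKM) in at
least one tissue (inclusive >=); the fraction-below check uses strict <.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 50.0
THRESHOLD_GRID = (10.0, 20.0, 50.0, 100.0)


def read_expression(path: str) -> pd.DataFrame:
    """TSV with gene rows and tissue columns; header required."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(df)
    return df


def validate_matrix(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative RPKM values")


def baseline_tissue(df: pd.DataFrame) -> tuple[str, pd.Series]:
    """Arg-min of the per-tissue means; ties go to column order (logged)."""
    if df.empty or df.shape[1] < 2:
        raise ValueError("need >=1 gene and >=2 tissues")
    means = df.mean(axis=0)
    best = means.min()
    tied = [c for c in df.columns if means[c] == best]
    if len(tied) > 1:
        log.info("baseline tie between %s; taking %s (column order)",
                 tied, tied[0])
    return tied[0], means


def fraction_below(df: pd.DataFrame, tissue: str, threshold: float) -> float:
    """Exact fraction of genes with value strictly below the threshold."""
    if tissue not in df.columns:
        raise ValueError(f"unknown tissue {tissue!r}")
    if df.empty:
        return 0.0
    return float((df[tissue] < threshold).mean())


def expressed_set(
    df: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    sort_tissue: str | None = None,
) -> list[str]:
    """Genes reaching >= threshold in >=1 tissue, sorted ascending by the
    chosen tissue (default: the tissue with the highest mean), ties by
    gene id."""
    if df.empty:
        return []
    if sort_tissue is None:
        sort_tissue = df.mean(axis=0).idxmax()
    sel = df[(df >= threshold).any(axis=1)]
    order = sorted(sel.index, key=lambda g: (sel.at[g, sort_tissue], g))
    return order


def peak_tissue(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene arg-max tissue and value; ties -> first tissue, flagged;
    all-zero genes flagged as silent."""
    rows = []
    for gene, vals in df.iterrows():
        vmax = vals.max()
        winners = [c for c in df.columns if vals[c] == vmax]
        rows.append({
            "gene_id": gene,
            "tissue": winners[0],
            "value": float(vmax),
            "tie": len(winners) > 1,
            "silent": bool(vmax == 0),
        })
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "value", "tie",
                                       "silent"])


def smallest_baseline_threshold(
    df: pd.DataFrame,
    tissue: str,
    grid: tuple[float, ...] = THRESHOLD_GRID,
    fraction: float = 0.95,
) -> float | None:
    """Smallest grid value t with fraction_below(tissue, t) > fraction -
    recomputes the usual '>95% of genes below baseline' threshold choice
    as a computation rather than a constant."""
    for t in sorted(grid):
        if fraction_below(df, tissue, t) > fraction:
            return t
    return None
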