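"""Post-processing of differential-expression statistics.

The differential tables themselves come from an upstream count model
(edgeR/DESeq2-style); this module applies the significance filters, ranking
statistics, percentile ranks, z-scaling, and GWAS risk-gene intersection used
downstream. Thresholds are strict inequalities: a gene is called only when
padj < padj_max and |log2FC| > lfc_min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cap for -log10(p) when p underflows to 0
LOGP_CAP = 308.0


@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes split by direction, with the thresholds used."""

    up: frozenset[str]
    down: frozenset[str]
    padj_max: float = 0.05
    lfc_min: float = 1.0
    n_rejected: int = 0  # rows dropped for NaN statistics

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down DEG sets overlap")

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down


def filter_degs(table: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0) -> DEGSet:
    """Select genes with padj < padj_max and |log2FC| > lfc_min (both strict).

    NaN statistics reject the row with a warning; an empty table yields an
    empty DEGSet.
    """
    if table.empty:
        return DEGSet(frozenset(), frozenset(), padj_max, lfc_min)
    bad = table["padj"].isna() | table["log2FC"].isna()
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} rows with NaN statistics", stacklevel=2)
    ok = table.loc[~bad]
    sig = ok.loc[(ok["padj"] < padj_max) & (ok["log2FC"].abs() > lfc_min)]
    up = frozenset(sig.loc[sig["log2FC"] > 0, "gene"])
    down = frozenset(sig.loc[sig["log2FC"] < 0, "gene"])
    return DEGSet(up, down, padj_max, lfc_min, n_rejected)


def rank_statistic(table: pd.DataFrame, mode: str = "signed_logp") -> pd.DataFrame:
    """Rank genes for preranked enrichment.

    mode='signed_logp' scores each gene sign(log2FC) * (-log10 p); mode='lfc'
    uses log2FC directly. Returns a DataFrame (gene, score) sorted by
    descending score with lexicographic gene-id tie-breaking; -log10(0) is
    capped at 308.
    """
    if table["gene"].duplicated().any():
        raise ValueError("duplicate gene ids")
    if mode == "signed_logp":
        with np.errstate(divide="ignore"):
            logp = -np.log10(table["pvalue"].to_numpy(dtype=float))
        logp = np.minimum(logp, LOGP_CAP)
        score = np.sign(table["log2FC"].to_numpy(dtype=float)) * logp
    elif mode == "lfc":
        score = table["log2FC"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    out = pd.DataFrame({"gene": table["gene"].to_numpy(), "score": score})
    return out.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def percentile_rank(values) -> np.ndarray:
    """Percentile rank in (0, 1]: rank(v) = #(values <= v) / n.

    The maximum element maps to exactly 1.0 and ties share a rank.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot percentile-rank an empty list")
    order = np.sort(arr)
    ranks = np.searchsorted(order, arr, side="right")
    return ranks / arr.size


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sample sd 1 (n-1 denominator).

    Constant rows become all-zero with a warning, mirroring how scale()
    handles zero-variance features.
    """
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows z-scored to zero", stacklevel=2)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=matrix.index, columns=matrix.columns)


def intersect_risk_genes(degs: DEGSet, table: pd.DataFrame, risk_list: set[str]) -> pd.DataFrame:
    """Rows of `table` for genes that are both DEGs and GWAS risk genes."""
    keep = degs.all & set(risk_list)
    return table.loc[table["gene"].isin(keep)].reset_index(drop=True)
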