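"""Discordant-perturbagen ranking against a disease gene signature.

Each perturbagen column of a signature library is compared with the query
signature by cosine similarity over their shared genes, both vectors
z-scored over the intersection first (equivalently, their Pearson
correlation). Perturbagens with negative similarity are candidate signature
reversers; they are ranked most-negative-first and aggregated by
mechanism-of-action (MOA) compound counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MIN_SHARED_GENES = 10


def similarity(query: pd.Series, perturbagen: pd.Series) -> float:
    """Cosine similarity over shared genes after per-vector z-scoring.

    Requires >= MIN_SHARED_GENES shared genes; raises otherwise.
    """
    shared = sorted(set(query.index) & set(perturbagen.index))
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(f"only {len(shared)} shared genes (< {MIN_SHARED_GENES})")
    a = query.loc[shared].to_numpy(dtype=float)
    b = perturbagen.loc[shared].to_numpy(dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant vector over shared genes")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def rank_discordant(library: pd.DataFrame, moa_labels: pd.Series,
                    query: pd.Series, top_n: int | None = None) -> pd.DataFrame:
    """Rank perturbagens discordant with the query signature.

    Only negative-similarity perturbagens are eligible; the list is sorted by
    similarity ascending (most negative first), ties broken by perturbagen
    id. Perturbagens sharing fewer than MIN_SHARED_GENES genes with the query
    are skipped with a note.
    """
    rows = []
    skipped = []
    for pert in library.columns:
        col = library[pert].dropna()
        try:
            sim = similarity(query, col)
        except ValueError:
            skipped.append(pert)
            continue
        if sim < 0:
            rows.append({"perturbagen": pert,
                         "moa": moa_labels.get(pert, "unknown"),
                         "similarity": sim})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} perturbagens with insufficient "
                      "gene overlap", stacklevel=2)
    out = pd.DataFrame(rows, columns=["perturbagen", "moa", "similarity"])
    out = out.sort_values(["similarity", "perturbagen"], kind="mergesort"
                          ).reset_index(drop=True)
    if top_n is not None:
        out = out.iloc[:top_n].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def moa_counts(discordant: pd.DataFrame) -> pd.Series:
    """Compound counts per MOA over a discordant list, sorted by count
    descending then label ascending."""
    if discordant.empty:
        return pd.Series(dtype=int, name="count")
    counts = discordant.groupby("moa").size().rename("count")
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    return counts.loc[order]
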