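"""Preranked GSEA, overrepresentation analysis, and their consensus.

GSEA uses the classic weighted Kolmogorov-Smirnov running sum over a ranked
gene list: walking down the list, hits increment the sum by
|score|^weight_p / sum_hits |score|^weight_p and misses decrement it by
1/(N - N_hits); the enrichment score (ES) is the signed maximum deviation.
Significance comes from a seeded gene-label permutation null, with the
normalized ES (NES) defined as ES divided by the mean |permuted ES| of the
same sign. ORA is the one-sided hypergeometric upper tail. The consensus
keeps only pathways significant in both analyses with concordant direction,
and a greedy Jaccard filter removes redundant terms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def running_sum_es(scores: np.ndarray, is_hit: np.ndarray, weight_p: float = 1.0) -> float:
    """ES of one gene set on a descending-ranked score vector.

    `is_hit` marks set members along the ranked list. Returns the signed
    maximum deviation of the running sum.
    """
    n = scores.size
    n_hits = int(is_hit.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight_p
    hit_total = w[is_hit].sum()
    steps = np.where(is_hit, w / hit_total if hit_total > 0 else 0.0, -1.0 / (n - n_hits))
    if hit_total == 0:  # all member scores exactly zero: uniform hit steps
        steps = np.where(is_hit, 1.0 / n_hits, steps)
    path = np.cumsum(steps)
    return float(path[np.argmax(np.abs(path))])


def _perm_es(scores: np.ndarray, n_hits: int, weight_p: float, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized label-permutation null: ES of n_perm random same-size sets."""
    n = scores.size
    w = np.abs(scores) ** weight_p
    # each row: a random choice of n_hits positions
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hits]
    hit = np.zeros((n_perm, n), dtype=bool)
    hit[np.arange(n_perm)[:, None], idx] = True
    hit_tot = (w * hit).sum(axis=1, keepdims=True)
    hit_tot[hit_tot == 0] = 1.0
    steps = np.where(hit, w / hit_tot, -1.0 / (n - n_hits))
    path = np.cumsum(steps, axis=1)
    flat = np.argmax(np.abs(path), axis=1)
    return path[np.arange(n_perm), flat]


def gsea_preranked(ranked: pd.DataFrame, sets: dict[str, tuple[str, set[str]]],
                   n_perm: int = 1000, weight_p: float = 1.0, seed: int = 0,
                   min_size: int = MIN_SET_SIZE, max_size: int = MAX_SET_SIZE) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    `ranked` is a (gene, score) frame sorted descending (see
    transcriptome.rank_statistic). Per set: ES, NES, a two-sided permutation
    p-value, BH-adjusted p, and direction ('up' for positive ES).
    """
    genes = ranked["gene"].to_numpy()
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list has duplicate genes")
    scores = ranked["score"].to_numpy(dtype=float)
    universe = set(genes)
    rng = np.random.default_rng(seed)

    rows = []
    for set_id in sorted(sets):
        _, members = sets[set_id]
        in_univ = members & universe
        if not in_univ:
            warnings.warn(f"set {set_id} has no genes in universe; skipped", stacklevel=2)
            continue
        if not min_size <= len(in_univ) <= max_size:
            continue
        is_hit = np.isin(genes, sorted(in_univ))
        es = running_sum_es(scores, is_hit, weight_p)
        k = int(is_hit.sum())
        null = _perm_es(scores, k, weight_p, n_perm, rng)
        # two-sided: |ES| against the full permutation null, +1 correction
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (1 + null.size)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        nes = es / np.mean(np.abs(same)) if same.size else np.nan
        rows.append({
            "set_id": set_id,
            "es": es,
            "nes": nes,
            "pvalue": float(p),
            "direction": "up" if es >= 0 else "down",
            "members_tested": k,
        })
    out = pd.DataFrame(rows, columns=["set_id", "es", "nes", "pvalue", "direction",
                                      "members_tested"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else out.get("pvalue")
    return out[["set_id", "es", "nes", "pvalue", "padj", "direction", "members_tested"]]


def ora(hits: set[str], universe: set[str], sets: dict[str, tuple[str, set[str]]],
        direction: str = "up", min_size: int = 1) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation test per gene set.

    P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set in universe|,
    n=|hits|); BH across the tested sets.
    """
    if not hits:
        raise ValueError("empty hit set: nothing to test")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    n_univ, n_hits = len(universe), len(hits)
    rows = []
    for set_id in sorted(sets):
        _, members = sets[set_id]
        in_univ = members & universe
        if len(in_univ) < min_size:
            continue
        overlap = len(in_univ & hits)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(in_univ), n_hits))
        rows.append({"set_id": set_id, "overlap": overlap,
                     "set_size": len(in_univ), "pvalue": min(1.0, p),
                     "direction": direction})
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "pvalue",
                                      "direction"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else out.get("pvalue")
    return out


def top_bottom_slice(ranked: pd.DataFrame, fraction: float = 0.10) -> tuple[set[str], set[str]]:
    """Top and bottom floor(fraction*N) genes of a descending-ranked list."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(ranked)
    k = int(np.floor(fraction * n))
    if k == 0:
        warnings.warn(f"slice of {fraction:.0%} of {n} genes is empty", stacklevel=2)
        return set(), set()
    genes = ranked["gene"].to_numpy()
    return set(genes[:k]), set(genes[-k:])


def consensus_pathways(gsea: pd.DataFrame, ora_res: pd.DataFrame,
                       padj_max: float = 0.05) -> list[str]:
    """Pathways significant (padj < padj_max) in both GSEA and ORA with
    concordant direction; sorted by set_id for determinism."""
    g = gsea.loc[gsea["padj"] < padj_max, ["set_id", "direction"]]
    o = ora_res.loc[ora_res["padj"] < padj_max, ["set_id", "direction"]]
    merged = g.merge(o, on="set_id", suffixes=("_gsea", "_ora"))
    keep = merged.loc[merged["direction_gsea"] == merged["direction_ora"], "set_id"]
    return sorted(keep)


def jaccard_index(a: set[str], b: set[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard_filter(results: pd.DataFrame, sets: dict[str, tuple[str, set[str]]],
                   max_jaccard: float = 0.5) -> pd.DataFrame:
    """Greedy redundancy filter: walk terms by ascending padj and keep a term
    only if its Jaccard index with every already-kept term is < max_jaccard."""
    ordered = results.sort_values(["padj", "set_id"], kind="mergesort")
    kept_ids: list[str] = []
    for set_id in ordered["set_id"]:
        members = sets[set_id][1]
        if all(jaccard_index(members, sets[k][1]) < max_jaccard for k in kept_ids):
            kept_ids.append(set_id)
    return results.loc[results["set_id"].isin(kept_ids)].reset_index(drop=True)
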