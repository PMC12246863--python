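"""Meta-clustering of pathway term embeddings with representative-term selection.

Dysregulated pathway terms, represented as fixed-dimension embedding vectors,
are grouped by agglomerative clustering under cosine distance with average
linkage; when k is not given, the silhouette-maximizing cut in 2..min(10, n-1)
is chosen. Each cluster is summarized by its most representative term (MRT):
the member with the highest cosine similarity to the cluster's unweighted
mean embedding (the centroid is not re-normalized). Cosine geometry makes the
assignments invariant to any global rotation of the embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score


@dataclass
class ClusterResult:
    labels: dict[str, int]           # term -> cluster
    mrts: dict[int, str]             # cluster -> most representative term
    centroids: dict[int, np.ndarray]
    k: int


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def most_representative_term(members: pd.DataFrame, centroid: np.ndarray) -> str:
    """Term with the highest cosine similarity to the centroid; ties break
    lexicographically on term id."""
    best: tuple[float, str] | None = None
    for term in sorted(members.index):
        sim = cosine_similarity(members.loc[term].to_numpy(), centroid)
        if best is None or sim > best[0]:
            best = (sim, term)
    return best[1]


def cluster_embeddings(emb: pd.DataFrame, k: int | str = "auto",
                       seed: int = 0) -> ClusterResult:
    """Cluster term embeddings (rows = terms) and pick per-cluster MRTs.

    Deterministic given the input order; `seed` is accepted for interface
    symmetry with the stochastic stages (agglomerative clustering needs none).
    """
    n = len(emb)
    if n < 2:
        raise ValueError("need at least 2 terms to cluster")
    X = emb.to_numpy(dtype=float)
    if (np.linalg.norm(X, axis=1) == 0).any():
        raise ValueError("zero embedding vectors are not allowed")

    if k == "auto":
        best = None
        for kk in range(2, min(10, n - 1) + 1):
            labels = AgglomerativeClustering(
                n_clusters=kk, metric="cosine", linkage="average").fit_predict(X)
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(X, labels, metric="cosine")
            if best is None or score > best[0] + 1e-12:
                best = (score, kk, labels)
        if best is None:
            raise ValueError("auto-k failed: no valid cut")
        k, labels = best[1], best[2]
    else:
        k = int(k)
        if not 1 <= k <= n:
            raise ValueError("k must be in 1..n_terms")
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = AgglomerativeClustering(
                n_clusters=k, metric="cosine", linkage="average").fit_predict(X)

    label_map = {term: int(c) for term, c in zip(emb.index, labels)}
    centroids, mrts = {}, {}
    for c in sorted(set(labels)):
        members = emb.loc[[t for t in emb.index if label_map[t] == c]]
        centroid = members.to_numpy(dtype=float).mean(axis=0)
        centroids[int(c)] = centroid
        mrts[int(c)] = most_representative_term(members, centroid)
    return ClusterResult(label_map, mrts, centroids, int(k))
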