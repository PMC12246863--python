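"""Synthetic multiomic inputs with planted ground truth.

Every pipeline input — DE tables, kinome-array runs, PPI networks, regulons,
perturbagen signature libraries and pathway-term embeddings — can be
generated here with a known planted structure (effect sizes, active kinases
and TFs, a connected high-prize module, signature reversers, embedding
clusters), so downstream recovery is scoreable without external data. All
generators are pure functions of their parameters and seed.

Default scales mirror the emulated experiment: 3 case and 3 control pooled
samples, technical triplicates on 3 chips, camera exposures of 10, 20, 50,
100 and 200 ms, DE null log2FCs with sd 0.25 and uniform null p-values
adjusted jointly with the planted genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import bh_adjust

DEFAULT_EXPOSURES = (10, 20, 50, 100, 200)
NULL_LFC_SD = 0.25


@dataclass
class GroundTruth:
    """Planted structure emitted alongside every generated dataset."""

    de_genes_up: frozenset[str] = frozenset()
    de_genes_down: frozenset[str] = frozenset()
    active_kinases: dict[str, float] = field(default_factory=dict)
    active_tfs: dict[str, float] = field(default_factory=dict)
    module_nodes: frozenset[str] = frozenset()
    reverser_ids: frozenset[str] = frozenset()
    cluster_labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# differential expression

def gen_de_table(n_genes: int, n_up: int, n_down: int, lfc_effect: float = 2.0,
                 seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """DE statistics table with n_up/n_down planted genes.

    Null genes: log2FC ~ N(0, 0.25), p ~ U(0,1). Planted genes:
    |log2FC| >= lfc_effect with tiny raw p, so after the joint BH adjustment
    their padj is < 0.01. Gene ids are G0000, G0001, ...
    """
    if n_genes < 0 or n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must be <= n_genes")
    if lfc_effect <= 0:
        raise ValueError("lfc_effect must be positive")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    lfc = rng.normal(0.0, NULL_LFC_SD, n_genes)
    pvals = rng.uniform(0.0, 1.0, n_genes)

    planted = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    lfc[up_idx] = lfc_effect + np.abs(rng.normal(0.0, NULL_LFC_SD, n_up))
    lfc[down_idx] = -(lfc_effect + np.abs(rng.normal(0.0, NULL_LFC_SD, n_down)))
    pvals[planted] = rng.uniform(1e-12, 1e-8, n_up + n_down)

    padj = bh_adjust(pvals) if n_genes else np.array([])
    table = pd.DataFrame({"gene": genes, "log2FC": lfc, "pvalue": pvals, "padj": padj})
    truth = GroundTruth(de_genes_up=frozenset(genes[up_idx]),
                        de_genes_down=frozenset(genes[down_idx]))
    return table, truth


# ---------------------------------------------------------------------------
# kinome array

def gen_kinase_map(n_kinases: int = 10, substrates_per_kinase: int = 8,
                   n_extra_peptides: int = 20, shared_fraction: float = 0.1,
                   seed: int = 0) -> dict[str, set[str]]:
    """Kinase -> substrate-peptide map over a synthetic chip.

    Peptides are P0000...; a fraction of substrates is shared between
    consecutive kinases (real substrate maps overlap).
    """
    rng = np.random.default_rng(seed)
    n_pep = n_kinases * substrates_per_kinase + n_extra_peptides
    peptides = [f"P{i:04d}" for i in range(n_pep)]
    kmap: dict[str, set[str]] = {}
    for k in range(n_kinases):
        start = k * substrates_per_kinase
        subs = set(peptides[start:start + substrates_per_kinase])
        n_shared = int(round(shared_fraction * substrates_per_kinase))
        if n_shared and k:
            prev = sorted(kmap[f"K{k - 1:03d}"])
            subs |= set(rng.choice(prev, size=min(n_shared, len(prev)), replace=False))
        kmap[f"K{k:03d}"] = subs
    return kmap


def chip_peptides(kinase_map: dict[str, set[str]], n_extra_peptides: int = 0) -> set[str]:
    """Peptide universe implied by a kinase map (all mapped peptides)."""
    return set().union(*kinase_map.values()) if kinase_map else set()


def gen_kinome_run(kinase_map: dict[str, set[str]], active_kinases,
                   shift: float = 1.0, n_samples_per_group: int = 3,
                   exposure_times=DEFAULT_EXPOSURES, noise_sd: float = 0.1,
                   n_chips: int = 3, n_extra_peptides: int = 20,
                   seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format kinome run with planted active kinases.

    Each peptide has a log-normal baseline slope; intensity grows linearly
    with exposure (slope scaled so the derived log2 value is
    log2(100*slope)). Substrates of active kinases carry a case-group slope
    multiplier of 2^shift; slope noise is log-normal with log2-sd noise_sd.
    Non-mapped chip peptides (N extra) dilute the significant set.
    """
    times = np.asarray(exposure_times, dtype=float)
    if times.size < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("exposure_times must be strictly increasing, length >= 2")
    active = dict.fromkeys(active_kinases, shift) if not isinstance(active_kinases, dict) \
        else dict(active_kinases)
    for k in active:
        if k not in kinase_map:
            raise ValueError(f"unknown kinase id: {k}")
    rng = np.random.default_rng(seed)

    peptides = sorted(chip_peptides(kinase_map))
    n0 = len(peptides)
    peptides += [f"X{i:04d}" for i in range(n_extra_peptides)]
    shifted: dict[str, float] = {}
    for k, s in active.items():
        for pep in kinase_map[k]:
            shifted[pep] = max(shifted.get(pep, 0.0), s)

    rows = []
    baselines = 2.0 ** rng.normal(1.0, 0.5, len(peptides))
    for pi, pep in enumerate(peptides):
        for group in ("case", "control"):
            eff = shifted.get(pep, 0.0) if group == "case" else 0.0
            for s in range(n_samples_per_group):
                sample = f"{group}-{s + 1}"
                for chip in range(1, n_chips + 1):
                    slope = baselines[pi] * 2.0 ** (eff + rng.normal(0.0, noise_sd))
                    intercept = 50.0
                    for t in times:
                        rows.append((pep, sample, group, f"chip-{chip}", t,
                                     intercept + slope * t))
    run = pd.DataFrame(rows, columns=["peptide", "sample", "group", "chip",
                                      "exposure_ms", "intensity"])
    truth = GroundTruth(active_kinases=active)
    return run, truth


# ---------------------------------------------------------------------------
# PPI network

def gen_ppi(n_nodes: int, mean_degree: float = 6.0, planted_module=(),
            high_conf: float = 0.9, seed: int = 0) -> tuple[nx.Graph, GroundTruth]:
    """Random PPI graph plus a connected planted module.

    Background: Erdős–Rényi with edge probability mean_degree/(n-1),
    confidences ~ U(0.15, 0.95). The planted module gets a random spanning
    tree plus extra internal edges, all with confidence >= high_conf. Module
    ids not of the generated form are added as extra nodes only if needed.
    """
    if not 0 < high_conf <= 1:
        raise ValueError("high_conf must be in (0, 1]")
    module = sorted(planted_module)
    if len(module) >= 2 and n_nodes < 2:
        raise ValueError("cannot plant a connected module on fewer than 2 nodes")
    rng = np.random.default_rng(seed)
    names = [f"N{i:04d}" for i in range(n_nodes)]
    # planted ids replace the first generated names
    for i, m in enumerate(module):
        if m not in names:
            names[i] = m
    nodes = sorted(set(names) | set(module))

    g = nx.Graph()
    g.add_nodes_from(nodes)
    p_edge = min(1.0, mean_degree / max(1, len(nodes) - 1))
    arr = np.array(nodes)
    for i in range(len(arr)):
        draw = rng.random(len(arr) - i - 1)
        for j_off in np.nonzero(draw < p_edge)[0]:
            j = i + 1 + j_off
            g.add_edge(arr[i], arr[j], confidence=float(rng.uniform(0.15, 0.95)))

    if len(module) >= 2:
        order = list(rng.permutation(module))
        for a, b in zip(order, order[1:]):  # random spanning tree
            g.add_edge(a, b, confidence=float(rng.uniform(high_conf, 1.0)))
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < 0.5:
                    a, b = module[i], module[j]
                    g.add_edge(a, b, confidence=float(
                        max(g[a][b]["confidence"], rng.uniform(high_conf, 1.0))
                        if g.has_edge(a, b) else rng.uniform(high_conf, 1.0)))
    truth = GroundTruth(module_nodes=frozenset(module))
    return g, truth


def gen_prized_instance(n_max: int = 10, edge_p: float = 0.4, tree: bool = False,
                        seed: int = 0):
    """Small random prized network for benchmarking the Steiner-forest solver.

    Node prizes are U(0,1) with 60 % probability (else 0); confidences
    U(0.1, 1); beta ~ U(0.5, 3), omega ~ U(0.2, 1.5). With tree=True the
    graph is a uniform random labeled tree.
    """
    from .integration import PrizedNetwork

    rng = np.random.default_rng(seed)
    n = int(rng.integers(3 if tree else 4, n_max + 1))
    if tree:
        g = nx.random_labeled_tree(n, seed=int(rng.integers(2 ** 31)))
    else:
        g = nx.gnp_random_graph(n, edge_p, seed=int(rng.integers(2 ** 31)))
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g})
    for u, v in g.edges:
        g[u][v]["confidence"] = float(rng.uniform(0.1, 1.0))
    for v in g.nodes:
        g.nodes[v]["prize"] = float(rng.uniform(0, 1)) if rng.random() < 0.6 else 0.0
    return PrizedNetwork(g, beta=float(rng.uniform(0.5, 3.0)),
                         omega=float(rng.uniform(0.2, 1.5)))


# ---------------------------------------------------------------------------
# regulons

def gen_regulons(n_tfs: int, targets_per_tf: int, active_tfs: dict[str, float],
                 n_genes: int = 2000, noise_sd: float = 1.0, seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Regulon table plus a matched gene-statistic vector.

    TF ids are TF000...; each regulon samples targets_per_tf genes without
    replacement with weights ±1 (80 % positive). A target of an active TF has
    its t-value shifted by activity x weight; all genes carry N(0, noise_sd)
    noise. Unknown TF ids in active_tfs raise.
    """
    if targets_per_tf > n_genes:
        raise ValueError("targets_per_tf exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    for t in active_tfs:
        if t not in tfs:
            raise ValueError(f"unknown TF id: {t}")

    stats = rng.normal(0.0, noise_sd, n_genes)
    rows = []
    for tf in tfs:
        targets = rng.choice(n_genes, size=targets_per_tf, replace=False)
        weights = rng.choice([1.0, -1.0], size=targets_per_tf, p=[0.8, 0.2])
        act = active_tfs.get(tf, 0.0)
        for gi, w in zip(targets, weights):
            rows.append((tf, genes[gi], w))
            if act:
                stats[gi] += act * w
    regulons = pd.DataFrame(rows, columns=["source", "target", "weight"])
    gene_stats = pd.Series(stats, index=pd.Index(genes, name="gene"), name="stat")
    truth = GroundTruth(active_tfs=dict(active_tfs))
    return regulons, gene_stats, truth


# ---------------------------------------------------------------------------
# perturbagen signatures

def gen_signature_library(query: pd.Series, n_perturbagens: int, n_reversers: int,
                          moa_labels, noise_sd: float = 0.5, seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Gene x perturbagen signature matrix with planted reversers.

    Reversers are -query plus N(0, noise_sd) noise and carry the first MOA
    label; null perturbagens are independent noise at the query's scale with
    MOAs drawn from the remaining labels.
    """
    if n_reversers > n_perturbagens:
        raise ValueError("n_reversers exceeds n_perturbagens")
    moa_labels = list(moa_labels)
    if not moa_labels:
        raise ValueError("need at least one MOA label")
    rng = np.random.default_rng(seed)
    q = query.astype(float)
    scale = float(q.std(ddof=0)) or 1.0
    perts = [f"PERT{i:04d}" for i in range(n_perturbagens)]
    reversers = perts[:n_reversers]

    cols = {}
    labels = {}
    null_moas = moa_labels[1:] or moa_labels
    for i, pert in enumerate(perts):
        if i < n_reversers:
            cols[pert] = -q.to_numpy() + rng.normal(0.0, noise_sd, len(q))
            labels[pert] = moa_labels[0]
        else:
            cols[pert] = rng.normal(0.0, scale, len(q))
            labels[pert] = null_moas[int(rng.integers(len(null_moas)))]
    lib = pd.DataFrame(cols, index=q.index)
    moa = pd.Series(labels, name="moa").loc[perts]
    truth = GroundTruth(reverser_ids=frozenset(reversers))
    return lib, moa, truth


# ---------------------------------------------------------------------------
# pathway-term embeddings

def gen_embeddings(n_terms: int, n_clusters: int, dim: int = 20,
                   separation: float = 0.5, noise_sd: float = 0.05,
                   seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Isotropic Gaussian term blobs around separated unit-norm centers.

    Centers are rejection-sampled until all pairwise cosine distances are
    >= separation. Terms T0000... are assigned to clusters round-robin.
    """
    if n_clusters < 1 or n_terms < n_clusters:
        raise ValueError("need n_terms >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        centers = rng.normal(size=(n_clusters, dim))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        cos = centers @ centers.T
        np.fill_diagonal(cos, -1.0)
        if (1.0 - cos.max()) >= separation or n_clusters == 1:
            break
    else:
        raise RuntimeError("could not sample sufficiently separated centers")

    terms = [f"T{i:04d}" for i in range(n_terms)]
    assign = {t: i % n_clusters for i, t in enumerate(terms)}
    vecs = np.stack([centers[assign[t]] + rng.normal(0.0, noise_sd, dim)
                     for t in terms])
    emb = pd.DataFrame(vecs, index=pd.Index(terms, name="term"),
                       columns=[f"d{j}" for j in range(dim)])
    return emb, GroundTruth(cluster_labels=assign)
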