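"""Configuration-driven orchestration of the full multiomic pipeline.

Stages run in a fixed order — transcriptome, enrichment, tf_activity,
kinome, integration, pathway_clustering, lincs — each reading its inputs
from the output directory (written either by `simulate` from the synthetic
generators or supplied as paths) and writing per-stage TSVs, a JSON summary
and a deterministic log. A single global seed fans out to per-stage seeds as
seed + stage index, so any stage can be re-run in isolation and two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as akio
from . import (enrichment, integration, kinome, lincs, pathway_clustering,
               synthetic, tf_activity, transcriptome)

SCHEMA_VERSION = 1
STAGES = ["transcriptome", "enrichment", "tf_activity", "kinome",
          "integration", "pathway_clustering", "lincs"]
#: seed offset per stage (simulate = 0)
STAGE_SEED_OFFSET = {name: i + 1 for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    outdir: str = "astrokin-out"
    seed: int = 0
    # thresholds (defaults are the printed study values)
    padj_max: float = 0.05
    lfc_min: float = 1.0
    peptide_lfc_cut: float = 0.2
    gsea_n_perm: int = 1000
    beta: float = 1.0
    omega: float = 2.0
    top_fraction: float = 0.10
    jaccard_max: float = 0.5
    lincs_top_n: int = 20
    # synthetic-generation block (used by `simulate`; ignored when inputs
    # are supplied as paths)
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.padj_max < 1:
            raise ValueError("padj_max must be in (0, 1)")
        if self.lfc_min < 0 or self.peptide_lfc_cut < 0:
            raise ValueError("fold-change cuts must be >= 0")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if not 0 < self.jaccard_max <= 1:
            raise ValueError("jaccard_max must be in (0, 1]")
        if self.beta < 0 or self.omega < 0:
            raise ValueError("beta and omega must be >= 0")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: {path} does not exist")


SYNTH_DEFAULTS = dict(
    n_genes=2000, n_up=60, n_down=40, lfc_effect=2.0,
    n_kinases=10, substrates_per_kinase=8, n_extra_peptides=20,
    n_active_kinases=2, kinase_shift=1.0, kinome_noise_sd=0.1,
    ppi_mean_degree=6.0, ppi_extra_nodes=40, ppi_high_conf=0.9,
    n_tfs=20, targets_per_tf=50, n_active_tfs=4, tf_activity_scale=3.0,
    n_gene_sets=30, gene_set_size=40,
    n_perturbagens=100, n_reversers=5,
    moa_labels=["reverser-moa", "moa-A", "moa-B", "moa-C", "moa-D"],
    n_terms=60, n_term_clusters=5, embedding_dim=20,
    n_risk_genes=25,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _inp(cfg: PipelineConfig, name: str, default_name: str) -> Path:
    return Path(cfg.inputs.get(name, Path(cfg.outdir) / "inputs" / default_name))


def simulate(cfg: PipelineConfig) -> dict:
    """Generate every synthetic input under <outdir>/inputs with planted truth."""
    p = {**SYNTH_DEFAULTS, **cfg.synthetic}
    seed = cfg.seed
    indir = Path(cfg.outdir) / "inputs"
    indir.mkdir(parents=True, exist_ok=True)

    de, de_truth = synthetic.gen_de_table(p["n_genes"], p["n_up"], p["n_down"],
                                          p["lfc_effect"], seed=seed)
    akio.write_de_table(de, indir / "de.tsv")

    kmap = synthetic.gen_kinase_map(p["n_kinases"], p["substrates_per_kinase"],
                                    p["n_extra_peptides"], seed=seed)
    akio.write_gmt({k: ("substrates", v) for k, v in kmap.items()},
                   indir / "kinase_map.gmt")
    active_kinases = sorted(kmap)[:p["n_active_kinases"]]
    run, kin_truth = synthetic.gen_kinome_run(
        kmap, active_kinases, shift=p["kinase_shift"],
        noise_sd=p["kinome_noise_sd"], n_extra_peptides=p["n_extra_peptides"],
        seed=seed)
    akio.write_kinome_run(run, indir / "kinome.csv")

    rng = np.random.default_rng(seed)
    # PPI over DEG hits + kinases + anonymous background nodes
    de_hits = de.loc[de["padj"] < cfg.padj_max, "gene"]
    module = sorted(de_truth.de_genes_up)[:10] + active_kinases
    n_nodes = len(de_hits) + p["n_kinases"] + p["ppi_extra_nodes"]
    g, _ = synthetic.gen_ppi(n_nodes, p["ppi_mean_degree"], module,
                             p["ppi_high_conf"], seed=seed)
    # relabel anonymous background nodes to the remaining hit/kinase ids
    anon = sorted(v for v in g.nodes if str(v).startswith("N"))
    real = [x for x in sorted(set(de_hits) | set(kmap)) if x not in g]
    mapping = dict(zip(anon, real))
    import networkx as nx
    g = nx.relabel_nodes(g, mapping)
    akio.write_string_edges(g, indir / "ppi.tsv")

    regs, gene_stats, tf_truth = synthetic.gen_regulons(
        p["n_tfs"], p["targets_per_tf"],
        _planted_tf_activities(p, seed), n_genes=p["n_genes"], seed=seed)
    akio.write_regulons(regs, indir / "regulons.tsv")
    gene_stats.rename("stat").rename_axis("gene").reset_index().to_csv(
        indir / "gene_stats.tsv", sep="\t", index=False)

    sets = _gen_gene_sets(list(de["gene"]), de_truth, p, rng)
    akio.write_gmt(sets, indir / "genesets.gmt")

    query = de.set_index("gene").loc[sorted(de_truth.de_genes_up
                                            | de_truth.de_genes_down), "log2FC"]
    lib, moa, sig_truth = synthetic.gen_signature_library(
        query, p["n_perturbagens"], p["n_reversers"], p["moa_labels"], seed=seed)
    akio.write_signature_matrix(lib, indir / "signatures.tsv")
    akio.write_moa_labels(moa, indir / "moa.tsv")

    emb, emb_truth = synthetic.gen_embeddings(p["n_terms"], p["n_term_clusters"],
                                              p["embedding_dim"], seed=seed)
    akio.write_embeddings(emb, indir / "embeddings.tsv")

    risk = sorted(rng.choice(sorted(de_truth.de_genes_up | de_truth.de_genes_down),
                             size=min(p["n_risk_genes"], p["n_up"] + p["n_down"]),
                             replace=False))
    akio.write_gene_list(risk, indir / "risk_genes.txt")

    truth = {
        "de_genes_up": sorted(de_truth.de_genes_up),
        "de_genes_down": sorted(de_truth.de_genes_down),
        "active_kinases": kin_truth.active_kinases,
        "active_tfs": tf_truth.active_tfs,
        "module_nodes": sorted(module),
        "reverser_ids": sorted(sig_truth.reverser_ids),
        "cluster_labels": emb_truth.cluster_labels,
    }
    with open(indir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def _planted_tf_activities(p: dict, seed: int) -> dict[str, float]:
    rng = np.random.default_rng(seed + 17)
    tfs = [f"TF{i:03d}" for i in range(p["n_tfs"])]
    chosen = sorted(rng.choice(tfs, size=p["n_active_tfs"], replace=False))
    signs = rng.choice([1.0, -1.0], size=len(chosen))
    return {t: float(s * p["tf_activity_scale"]) for t, s in zip(chosen, signs)}


def _gen_gene_sets(universe, de_truth, p, rng) -> dict:
    sets = {}
    for i in range(p["n_gene_sets"]):
        members = set(rng.choice(universe, size=p["gene_set_size"], replace=False))
        sets[f"SET{i:03d}"] = ("random", members)
    sets["SET_PLANTED_UP"] = ("planted up", set(de_truth.de_genes_up))
    sets["SET_PLANTED_DOWN"] = ("planted down", set(de_truth.de_genes_down))
    return sets


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the pipeline stages in order; returns the summary dict.

    Stage outputs land under <outdir>/<stage>/. Failures halt with the stage
    name; a MANIFEST file records which stages completed.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": cfg.seed,
                     "stages": {}}
    log_lines: list[str] = []
    manifest: list[str] = []
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            try:
                info = _STAGE_FUNCS[stage](cfg, out)
            except Exception as exc:
                raise PipelineError(stage, exc) from exc
            summary["stages"][stage] = info
            manifest.append(stage)
            log_lines.append(f"stage={stage} status=ok "
                             + " ".join(f"{k}={v}" for k, v in sorted(info.items())
                                        if np.isscalar(v)))
    finally:
        status = "complete" if manifest == [s for s in STAGES if s in stages] \
            else "INCOMPLETE"
        (out / "MANIFEST").write_text(
            "\n".join([f"status: {status}", *manifest]) + "\n", encoding="utf-8")
        (out / "run.log").write_text("".join(l + "\n" for l in log_lines),
                                     encoding="utf-8")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


# ---------------------------------------------------------------------------
# stage implementations

def _stage_dir(out: Path, stage: str) -> Path:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_transcriptome(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "transcriptome")
    de = akio.read_de_table(_inp(cfg, "de", "de.tsv"))
    degs = transcriptome.filter_degs(de, cfg.padj_max, cfg.lfc_min)
    ranked = transcriptome.rank_statistic(de, mode="signed_logp")
    ranked_lfc = transcriptome.rank_statistic(de, mode="lfc")
    risk_path = _inp(cfg, "risk_genes", "risk_genes.txt")
    risk = akio.read_gene_list(risk_path) if Path(risk_path).exists() else set()
    overlap = transcriptome.intersect_risk_genes(degs, de, risk)

    akio.write_gene_list(degs.up, d / "degs_up.txt")
    akio.write_gene_list(degs.down, d / "degs_down.txt")
    ranked.to_csv(d / "ranked_signed_logp.tsv", sep="\t", index=False)
    ranked_lfc.to_csv(d / "ranked_lfc.tsv", sep="\t", index=False)
    overlap.to_csv(d / "risk_overlap.tsv", sep="\t", index=False)
    return {"n_up": len(degs.up), "n_down": len(degs.down),
            "n_degs": len(degs.all), "n_risk_overlap": len(overlap)}


def _stage_enrichment(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "enrichment")
    de = akio.read_de_table(_inp(cfg, "de", "de.tsv"))
    sets = akio.read_gmt(_inp(cfg, "gene_sets", "genesets.gmt"))
    seed = cfg.seed + STAGE_SEED_OFFSET["enrichment"]

    ranked = transcriptome.rank_statistic(de, mode="signed_logp")
    gsea = enrichment.gsea_preranked(ranked, sets, n_perm=cfg.gsea_n_perm, seed=seed)
    ranked_lfc = transcriptome.rank_statistic(de, mode="lfc")
    top, bottom = enrichment.top_bottom_slice(ranked_lfc, cfg.top_fraction)
    universe = set(de["gene"])
    ora_up = enrichment.ora(top, universe, sets, direction="up")
    ora_down = enrichment.ora(bottom, universe, sets, direction="down")
    ora_all = pd.concat([ora_up, ora_down], ignore_index=True)
    ora_all["padj"] = enrichment.bh_adjust(ora_all["pvalue"])

    consensus = enrichment.consensus_pathways(gsea, ora_all, cfg.padj_max)
    sig = gsea.loc[gsea["set_id"].isin(consensus)]
    filtered = enrichment.jaccard_filter(sig, sets, cfg.jaccard_max)

    gsea.to_csv(d / "gsea.tsv", sep="\t", index=False)
    ora_all.to_csv(d / "ora.tsv", sep="\t", index=False)
    filtered.to_csv(d / "consensus_filtered.tsv", sep="\t", index=False)
    (d / "consensus.txt").write_text("".join(s + "\n" for s in consensus),
                                     encoding="utf-8")
    return {"n_gsea_sig": int((gsea["padj"] < cfg.padj_max).sum()),
            "n_ora_sig": int((ora_all["padj"] < cfg.padj_max).sum()),
            "n_consensus": len(consensus),
            "n_after_jaccard": len(filtered)}


def _stage_tf_activity(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "tf_activity")
    regs = akio.read_regulons(_inp(cfg, "regulons", "regulons.tsv"))
    stats_df = pd.read_csv(_inp(cfg, "gene_stats", "gene_stats.tsv"), sep="\t")
    gene_stats = stats_df.set_index("gene")["stat"]
    acts = tf_activity.ulm_score(gene_stats, regs)
    activated, deactivated = tf_activity.classify_tfs(acts)
    acts.to_csv(d / "tf_activity.tsv", sep="\t", index=False)
    top_tf = acts.loc[acts["score"].idxmax(), "tf"] if len(acts) else None
    return {"n_tfs_scored": len(acts), "n_activated": len(activated),
            "n_deactivated": len(deactivated), "top_tf": top_tf}


def _stage_kinome(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "kinome")
    run = akio.read_kinome_run(_inp(cfg, "kinome", "kinome.csv"))
    kmap = {k: v for k, (_, v) in akio.read_gmt(
        _inp(cfg, "kinase_map", "kinase_map.gmt")).items()}
    seed = cfg.seed + STAGE_SEED_OFFSET["kinome"]

    values = kinome.peptide_signal(run)
    stats = kinome.peptide_lfc(values, cfg.peptide_lfc_cut)
    per_sample = values.groupby(["sample", "group"])["value"].mean().reset_index()
    t, p = kinome.global_phospho_test(
        per_sample.loc[per_sample["group"] == "case", "value"],
        per_sample.loc[per_sample["group"] == "control", "value"])

    chip = set(stats["peptide"])
    sig = set(stats.loc[stats["significant"], "peptide"])
    krsa_res = kinome.krsa(sig, chip, kmap, seed=seed)
    kea = kinome.rank_enrichment_scorer(stats, kmap)
    uka = kinome.substrate_shift_scorer(stats, kmap)
    consensus = kinome.harmonize(
        {"krsa": krsa_res.set_index("kinase")["z"].abs(),
         "uka": uka.set_index("kinase")["abs_t"],
         "kea3": kea.set_index("kinase")["pvalue"]},
        {"krsa": True, "uka": True, "kea3": False})

    stats.drop(columns=["chip_lfcs"]).to_csv(d / "peptide_stats.tsv", sep="\t",
                                             index=False)
    krsa_res.to_csv(d / "krsa.tsv", sep="\t", index=False)
    uka.to_csv(d / "uka.tsv", sep="\t", index=False)
    kea.to_csv(d / "kea3.tsv", sep="\t", index=False)
    consensus.to_csv(d / "consensus.tsv", sep="\t", index=False)
    return {"n_peptides": len(stats), "n_significant": int(stats["significant"].sum()),
            "global_t": round(float(t), 6), "global_p": round(float(p), 6),
            "n_high_confidence": int((consensus["confidence"] == "high").sum()),
            "n_medium_confidence": int((consensus["confidence"] == "medium").sum())}


def _stage_integration(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "integration")
    de = akio.read_de_table(_inp(cfg, "de", "de.tsv"))
    g = akio.read_string_edges(_inp(cfg, "ppi", "ppi.tsv"))
    consensus = pd.read_csv(out / "kinome" / "consensus.tsv", sep="\t")
    kin_hits = consensus.loc[consensus["confidence"].isin(["high", "medium"])]
    de_hits = de.loc[de["padj"] < cfg.padj_max]

    prized = integration.assign_prizes(g, de_hits, kin_hits,
                                       beta=cfg.beta, omega=cfg.omega)
    forest = integration.pcsf_solve(prized)
    ranking, top_slice = integration.rank_nodes(forest, prized, cfg.top_fraction)

    sets = akio.read_gmt(_inp(cfg, "gene_sets", "genesets.gmt"))
    ora_top = None
    if top_slice:
        universe = set(g.nodes)
        ora_top = enrichment.ora(set(top_slice), universe, sets, direction="up")
        ora_top.to_csv(d / "top_nodes_ora.tsv", sep="\t", index=False)

    ranking.to_csv(d / "node_ranking.tsv", sep="\t", index=False)
    edges = pd.DataFrame(sorted(forest.edges), columns=["node1", "node2"])
    edges.to_csv(d / "forest_edges.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(sorted((v, forest.labels[v]) for v in forest.nodes),
                         columns=["node", "label"])
    nodes.to_csv(d / "forest_nodes.tsv", sep="\t", index=False)
    return {"n_forest_nodes": len(forest.nodes), "n_forest_edges": len(forest.edges),
            "n_trees": forest.n_trees, "objective": round(forest.objective, 6),
            "n_hidden": sum(1 for v in forest.nodes
                            if forest.labels[v] == "hidden"),
            "n_top_slice": len(top_slice)}


def _stage_pathway_clustering(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "pathway_clustering")
    emb = akio.read_embeddings(_inp(cfg, "embeddings", "embeddings.tsv"))
    res = pathway_clustering.cluster_embeddings(emb, k="auto")
    rows = [{"term": t, "cluster": c, "is_mrt": res.mrts[c] == t}
            for t, c in sorted(res.labels.items())]
    pd.DataFrame(rows).to_csv(d / "clusters.tsv", sep="\t", index=False)
    return {"n_terms": len(res.labels), "k": res.k,
            "mrts": ",".join(res.mrts[c] for c in sorted(res.mrts))}


def _stage_lincs(cfg: PipelineConfig, out: Path) -> dict:
    d = _stage_dir(out, "lincs")
    lib = akio.read_signature_matrix(_inp(cfg, "signatures", "signatures.tsv"))
    moa = akio.read_moa_labels(_inp(cfg, "moa", "moa.tsv"))
    de = akio.read_de_table(_inp(cfg, "de", "de.tsv"))
    degs = transcriptome.filter_degs(de, cfg.padj_max, cfg.lfc_min)
    query = de.set_index("gene").loc[sorted(degs.all), "log2FC"]
    discordant = lincs.rank_discordant(lib, moa, query)
    top = discordant.iloc[:cfg.lincs_top_n]
    counts = lincs.moa_counts(top)
    discordant.to_csv(d / "discordant.tsv", sep="\t", index=False)
    counts.rename_axis("moa").reset_index().to_csv(d / "moa_counts.tsv", sep="\t",
                                                   index=False)
    return {"n_discordant": len(discordant),
            "top_perturbagen": discordant["perturbagen"].iloc[0]
            if len(discordant) else None,
            "top_moa": counts.index[0] if len(counts) else None}


_STAGE_FUNCS = {
    "transcriptome": _stage_transcriptome,
    "enrichment": _stage_enrichment,
    "tf_activity": _stage_tf_activity,
    "kinome": _stage_kinome,
    "integration": _stage_integration,
    "pathway_clustering": _stage_pathway_clustering,
    "lincs": _stage_lincs,
}
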