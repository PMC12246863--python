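# astrokin

Multiomic integration of transcriptome and kinome-array profiling for
iPSC-derived astrocyte disease models — differential-expression
post-processing, enrichment consensus, transcription-factor activity
inference, upstream-kinase inference with cross-scorer consensus,
prize-collecting Steiner-forest network integration, pathway-embedding
meta-clustering, and discordant-perturbagen ranking — exercised end to end on
synthetic data with planted ground truth.

## Who this is for

Disease-model studies increasingly pair bulk RNA-seq with serine/threonine
peptide-array kinomics on the same lines (e.g. patient-derived astrocytes
versus matched controls). Each omic alone yields a hit list; the harder
question is which molecular hubs the two layers *jointly* implicate, and
which compounds might reverse the expression signature. `astrokin`
implements that analysis path as a single reproducible pipeline, and — since
such datasets are rarely deposited — ships a first-class synthetic-data
module so every stage can be validated against planted truth.

## The methods at the core

**DEG filtering and ranking.** Genes are called at strict thresholds
adj. *p* < 0.05 and |log2FC| > 1 (Benjamini–Hochberg adjustment wherever an
FDR appears). Preranked lists use sign(log2FC)·(−log10 *p*) by default, or
plain log2FC.

**Enrichment consensus.** Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum: walking the ranked list, set members add
|s|^p / Σ_hits |s|^p and non-members subtract 1/(N − N_hits); the enrichment
score ES is the signed maximum deviation, with significance from a seeded
gene-label permutation null and NES = ES / mean |same-sign permuted ES|. ORA
is the one-sided hypergeometric upper tail on the top and bottom 10 % of the
log2FC ranking. Only pathways significant in both analyses with concordant
direction are reported; redundant terms are removed greedily at Jaccard
index ≥ 0.5.

**TF activity (ULM).** For each transcription factor, genome-wide gene
statistics are regressed on the TF's signed regulon weight vector (zero for
non-targets) with an intercept; the slope's *t*-statistic is the activity
score — positive means activation, negative means inhibition.

**Upstream-kinase inference.** Per-peptide signal is
log2(max(100·slope, 1)) of the intensity–exposure OLS fit; peptides with
case-vs-control |log2FC| > 0.2 are significant. Three scorers then rank
kinases: a random-sampling Z-score of the significant-substrate count
(KRSA-style, the primary scorer), a one-sided substrate-enrichment Fisher
test, and a one-sample *t* of substrate log2FCs. Scores become percentile
ranks and quartiles; a kinase is *high* confidence in the top quartile of
all three scorers, *medium* with the primary in the top quartile and both
others in the top two.

**Network integration (PCSF).** Omic hits are prized on a PPI network
(transcriptomic: percentile rank of |log2FC| among hits; kinomic: mean
consensus score; dual hits take the max) with edge costs 1 − confidence + ε.
The solver seeks the forest *F* minimizing

    Σ_{v∉F} β·p(v)  +  Σ_{e∈F} c(e)  +  ω·(# trees)

via greedy growth, tree merging, and an exact dynamic-programming prune of
each candidate tree (exact on acyclic inputs); an exhaustive-enumeration
oracle checks it on small instances. Forest nodes are ranked by the average
of prize and eigenvector centrality; the top 10 % feed ORA and the full
ranking feeds GSEA. Zero-prize nodes that the forest interpolates are
labelled *hidden*.

**Pathway meta-clustering.** Dysregulated pathway-term embeddings are
clustered agglomeratively under cosine distance (average linkage,
silhouette-chosen k); each cluster is summarized by its most representative
term — the member with the highest cosine similarity to the cluster's mean
embedding.

**Discordant perturbagens.** Each library signature is compared with the
disease signature by cosine similarity over shared genes after per-vector
z-scoring (= Pearson correlation); negative-similarity compounds are ranked
most-discordant-first and aggregated by mechanism-of-action counts.

## Worked example

Run the full pipeline on synthetic inputs (100 planted DEGs, 2 active
kinases, 4 active TFs, 5 signature reversers, 5 embedding clusters):

```bash
astrokin run --seed 11 --outdir demo
```

which prints, per stage (abridged):

```json
"transcriptome":       {"n_up": 60, "n_down": 40, "n_degs": 100, "n_risk_overlap": 25}
"enrichment":          {"n_gsea_sig": 2, "n_ora_sig": 2, "n_consensus": 2}
"tf_activity":         {"n_tfs_scored": 20, "n_activated": 3, "n_deactivated": 1}
"kinome":              {"n_peptides": 100, "n_significant": 16,
                        "global_t": 39.27958, "n_high_confidence": 2}
"integration":         {"n_forest_nodes": 97, "n_trees": 1,
                        "objective": 19.564067, "n_hidden": 10}
"pathway_clustering":  {"n_terms": 60, "k": 5}
"lincs":               {"n_discordant": 55, "top_perturbagen": "PERT0002"}
```

Reading it: the DEG filter recovers exactly the 100 planted genes (60 up,
40 down); both planted gene sets survive the GSEA∩ORA consensus; both
planted kinases reach high consensus confidence; the Steiner forest joins
97 evidence nodes into one tree, interpolating 10 hidden connectors; the
embedding clusterer picks k = 5 as planted; and the most-discordant
perturbagens are the planted reversers. Per-stage TSVs, `summary.json`,
`run.log` and a `MANIFEST` land under `demo/`; two runs with the same seed
are byte-identical.

`astrokin simulate` writes the synthetic inputs only, `astrokin stage
<name>` re-runs one stage, and `astrokin report` reprints the summary. A
YAML config (`-c config.yaml`) overrides any threshold (padj_max, lfc_min,
peptide_lfc_cut, β, ω, top_fraction, jaccard_max, …), supplies real input
paths in place of the generators, and sets generator sizes.

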