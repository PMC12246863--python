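# Methods

## Scope and data model

`astrokin` post-processes *derived* omic statistics: a differential
expression table (gene, log2FC, p, BH-adjusted p) as produced by an
edgeR/DESeq2-style count model, and a long-format kinome-array run
(peptide × sample × chip × exposure × intensity) as produced by a
serine/threonine peptide chip imaged at increasing camera exposures.
Count-level RNA modelling and chip image processing are upstream of this
package and out of scope. All interchange formats are plain text (TSV/CSV,
GMT, STRING-style edge lists with 0–1000 integer scores).

## Thresholds and their semantics

| parameter | default | meaning |
|---|---|---|
| `padj_max` | 0.05 | DEG call, adjusted p (strict `<`) |
| `lfc_min` | 1.0 | DEG call, absolute log2FC (strict `>`) |
| `peptide_lfc_cut` | 0.2 | peptide phosphorylation call, log2 units (strict `>`) |
| `top_fraction` | 0.10 | ORA slices and forest-node slice (floor of N·fraction) |
| `jaccard_max` | 0.5 | redundancy filter keeps a term only if J < 0.5 vs all kept |
| `gsea_n_perm` | 1000 | gene-label permutations per set |
| `beta` (β) | 1.0 | prize scale in the PCSF objective |
| `omega` (ω) | 2.0 | per-tree penalty in the PCSF objective |

All threshold comparisons are strict, so boundary values (padj = 0.05,
|log2FC| = 1, |peptide LFC| = 0.2) are excluded; the tests pin this down
with boundary fixtures. Multiple testing is Benjamini–Hochberg everywhere an
adjusted p or FDR appears.

## Enrichment

Preranked GSEA implements the weighted KS running sum with exponent
`weight_p = 1`: hit increments |score|^p normalized by the in-set total,
miss decrements 1/(N − N_hits); ES is the signed maximum deviation. The null
permutes gene labels (equivalently, redraws same-size sets), fresh draws for
every set; sharing one null across same-size sets would correlate their
p-values and distort calibration, so it is deliberately not done. The
p-value is two-sided — |ES| against the full permutation null with the
(1 + k)/(1 + n_perm) correction — and NES divides ES by the mean |permuted
ES| of the same sign (classic normalization). Set-size limits are 5–500.
ORA is the hypergeometric upper tail; its closed form is cross-checked in
the tests against exhaustive enumeration on small universes. The consensus
keeps pathways significant in both GSEA and ORA with concordant direction,
then filters redundancy greedily by ascending adjusted p.

## TF activity

The univariate linear model regresses all genes' statistics on one TF's
weight vector with an intercept (so the score is invariant to global shifts
of the statistics) and reports the slope t-statistic (N − 2 df). t is
scale-free in y. Exact fits (SE → 0) are capped at ±1e6 and flagged rather
than propagating infinities. TFs with fewer than `min_targets = 5` covered
targets, or degenerate weight vectors, are skipped with a warning.

## Kinome processing

Per-peptide signal is `log2(max(100 · slope, 1))` where slope is the OLS
slope of intensity on exposure time. The vendor's exact image-to-number
transform is proprietary; this exposure-slope convention is the standard
one for the platform, is fully testable (an intensity line of slope 2
gives exactly log2(200)), and floors negative/flat slopes to 0 with a flag.
Per-sample values average the technical chips; per-chip fold changes are
retained with the maximum-|LFC| chip identified, matching the
waterfall-plot convention for triplicate chips.

Three scorers are deliberately independent in mechanism:

* **Random-sampling Z** (primary): observed significant-substrate count vs
  n_iter uniform draws without replacement from the chip (the finite peptide
  pool makes without-replacement the right null; its mean/variance converge
  to the hypergeometric closed form, which the tests assert within 3
  Monte-Carlo SEs). Zero-variance nulls leave Z missing.
* **Substrate-enrichment p**: hypergeometric upper tail of the 2×2
  significant × substrate table (≡ one-sided Fisher), BH across kinases.
  This is an open stand-in for an external enrichment service with the same
  interface.
* **Substrate-shift t**: one-sample t of substrate LFCs against 0. This is a
  documented stand-in for the vendor's proprietary upstream-kinase tool.

Peptides mapped to several kinases count for each. Harmonization orients
every score so higher = stronger, percentile-ranks within scorer
(rank(v) = #{values ≤ v}/n, so the maximum is exactly 1), bins into
quartiles (4 = top), and assigns confidence: *high* iff quartile 4 in all
three; *medium* iff the primary scorer is quartile 4 and both others ≥ 3;
*low* otherwise, including any kinase missing from a scorer (flagged). The
mean of the per-scorer percentiles is the kinase's consensus score and its
node prize downstream.

## Network integration

Edge costs are `1 − confidence + ε` (ε = 1e-6). The alternative reading
1/confidence is unbounded as confidence → 0 and distorts path costs; the
bounded form is monotone in confidence and keeps the objective on the prize
scale. Transcriptomic prizes are percentile ranks of |log2FC| *among hits*
(so a lone hit gets prize 1), kinomic prizes are mean consensus scores, and
dual-evidence nodes take the max — the stronger evidence should not be
diluted by averaging.

The solver minimizes Σ_{v∉F} β·p(v) + Σ_{e∈F} c(e) + ω·#trees. Strategy:

1. **Growth.** Repeatedly apply the globally best improving move among:
   open a singleton tree at an unclaimed terminal (Δ = ω − β·p); connect an
   unclaimed terminal to an existing tree along the cheapest
   prize-discounted path; or join two unclaimed terminals into a new tree.
   The pairwise move matters: two medium prizes can jointly justify a tree
   that neither justifies alone, a case plain one-terminal greedy misses.
2. **Merging.** Connect two trees whenever the cheapest path between them
   beats one ω.
3. **Pruning.** Each candidate node group is realized as the minimum
   spanning tree of its induced subgraph and then pruned by an exact
   tree dynamic program: B(v) = best with v's component open upward,
   A(v) = min(B(v) + ω, β·p(v) + Σ A(children)). The DP may split a tree —
   important when ω is smaller than an internal edge — and is the exact
   optimum within a tree, so acyclic inputs are solved exactly.

Ties break on sorted node ids; given the seed-free deterministic inputs the
solver is fully reproducible. The brute-force oracle enumerates node
subsets and, per subset, takes the MST of the subset graph augmented with a
virtual root joined to every node at cost ω (each root edge opens one
tree); this is the exact cheapest forest for that subset. The naive
"MST per induced component" is *not* optimal for small ω and was rejected.

Eigenvector centrality is power iteration on the confidence-weighted
adjacency of the largest connected component, with an identity shift
(A + I) — trees are bipartite and unshifted iteration oscillates between
the ±λ pair — normalized so the maximum node scores 1; nodes outside the
largest component score 0. Node ranking averages prize and centrality;
centrality is computed on the solved forest, whose topology is what the
ranking describes.

## Pathway meta-clustering

Agglomerative clustering, cosine distance, average linkage; with k = auto
the silhouette-maximizing cut in 2..min(10, n−1) is chosen (first maximum on
ties). Centroids are unweighted member means, not re-normalized, and the
most representative term is the argmax of cosine similarity to the
centroid with lexicographic tie-breaks. Cosine geometry makes assignments
invariant to global rotations, which the tests verify with a random
orthonormal rotation.

## Perturbagen discordance

Similarity is cosine over the shared-gene intersection after z-scoring each
vector over those genes — equivalently the Pearson correlation — bounded,
symmetric, scale-free, and exactly −1 for a noise-free antipodal signature.
A minimum overlap of 10 shared genes is required; smaller overlaps skip the
perturbagen with a note. Only negative similarities are eligible for the
discordant ranking. MOA aggregation counts compounds per label over the
top-ranked discordant slice (pipeline default: top 20).

## Synthetic data: what it emulates, and what it does not

The generators mirror the emulated study design: 3 case and 3 control
samples, technical triplicates on 3 chips, exposures 10/20/50/100/200 ms,
null log2FCs ~ N(0, 0.25) with Uniform(0,1) null p-values BH-adjusted
*jointly* with planted genes (a real table is adjusted once), kinome noise
log-normal on intensity slopes (intensities are positive; log2 downstream),
planted substrate shifts in log2 units, Erdős–Rényi PPI backgrounds with a
connected high-confidence planted module, ±1 regulon weights (80 %
positive), signature reversers as −query + noise, and isotropic Gaussian
embedding blobs around separation-checked unit centers.

Passing on these inputs demonstrates the *machinery* — filters, scorers,
solver, rankings — recovers planted structure at realistic noise. It does
not demonstrate robustness to what real data add: correlated genes,
batch/line effects, heavy-tailed intensity noise, biased regulon and
substrate annotations, or hub-dominated scale-free PPI topology. Default
problem sizes (2000 genes, ~100-peptide chip, 20 TFs, 100 perturbagens,
60 terms) are chosen so a full synthetic run completes in seconds on one
CPU while leaving all recovery margins wide.

## Numerical choices and degenerate inputs

* −log10(p) capped at 308 (double underflow); capped t-scores flagged.
* Percentile rank of the maximum is exactly 1.0; ties share ranks.
* Constant rows z-score to zero with a warning rather than NaN.
* Empty DEG tables yield empty sets, not errors; empty ORA hit sets are an
  error (nothing to test).
* All-zero prizes yield the empty forest with objective 0.
* Welch's t on two zero-variance equal samples returns (0, 1).
* Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage seeds as global seed + stage index so stages re-run in
  isolation reproducibly, and summaries/logs contain no timestamps so two
  runs are byte-identical.

## Verification design

Each operation is checked against an independent route: the GSEA running
sum against a naive re-walk and an exhaustively hand-computed 8-gene
fixture; ORA against enumeration; the sampling null against hypergeometric
moments; the solver against subset enumeration (and tree-DP exactness
against the same oracle on random trees); the confidence rule against a
direct transcription over all 64 quartile triples; clustering against
planted labels via adjusted Rand. One statistical subtlety: the KS distance
between 200 permutation p-values and Uniform(0,1) has ~4 % probability of
exceeding 0.1 even under perfect uniformity (0.1 is essentially the 4 %
Kolmogorov critical point at n = 200), so the calibration check reports the
median KS over three independent 200-set calibrations — a lower-variance
estimate of the same distance.

## Known limitations

* The vendor image transform and proprietary upstream-kinase scorer are
  replaced by documented stand-ins with the same interfaces; the scorer
  slot is pluggable if exact replacements become available.
* The PCSF solver is a heuristic on cyclic graphs; optimality is verified
  only against ≤ 12-node enumeration (exact on trees by construction).
* Gene sets are flat; no GO DAG propagation.
* Embeddings are inputs; the package does not train term embeddings.
* No stratification of perturbagen signatures by cell line, dose or time.
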