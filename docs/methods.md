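# Methods

This note documents the models, estimators, defaults and design choices in
`nichecomm`, and what the synthetic-data tests do and do not demonstrate.

## The communication model

For a focal population (e.g. NSCs receiving signals) and a partner
population (e.g. the surrounding niche), each curated ligand–receptor pair
contributes, to each focal cell *c*,

```
s_p(c) = x_c(g_focal) · m_partner(g_partner)
```

where `x_c` is the cell's normalized expression ("TPM" semantics: per-cell
counts scaled to 10^6; 3'-tag UMI data carry no gene-length bias, so no
length term is used) and `m_partner` is the partner population's mean
normalized expression of the opposite side of the pair. The global score is
the sum over pairs. Properties that follow directly and are property-tested:
scores are nonnegative, additive over pairs, and exactly linear in the
partner means (scaling all partner ligands by λ scales every receptor-side
score by λ).

**Partner means** are computed within each sample and then averaged across
samples, so a large sample cannot dominate an age-group contrast. Per-age
score summaries restrict both focal and partner populations to cells of
that age, giving an age-matched niche.

**Silent cells** are focal cells with global score exactly zero — the cell
expresses none of the focal-side genes. This definition is scale-free: any
normalization or rescaling preserves it.

**nMI edges.** Co-expression of a ligand and receptor across cells is
summarized by plug-in normalized mutual information on discretized
expression: default discretization is detected/not-detected (an
equal-frequency 3-bin quantile option exists), MI is normalized by the
arithmetic mean of the two marginal entropies (min and sqrt normalizations
are available). A zero-entropy marginal makes nMI 0 by definition, flagged
as degenerate. The estimator is the uncorrected plug-in; with the default
binary discretization and hundreds of cells its bias (~1/2n nats) is
negligible relative to the planted signals, so no bias correction is
applied.

**Differential LR network.** For one focal type, the Wilcoxon old-vs-young
test is run on all LR genes within that type; every pair with a
differentially expressed ligand or receptor (BH q ≤ q_max, default 0.05)
becomes an edge carrying gene-wise log2 fold-changes (all-cell means by
default; an expressing-cells-only flag exists for per-gene age trends),
direction, an nMI weight computed over pooled focal+partner cells, and the
partner types whose mean ligand expression exceeds a floor.

## Differential statistics

- **DEG test**: two-sided Wilcoxon rank-sum on normalized values. Groups of
  ≤ 8 cells use exact enumeration of all rank splits (midranks, two-sided by
  symmetric deviation); larger groups use the tie-corrected normal
  approximation. Genes detected in ≥ `min_fraction` (default 0.1) of either
  group are tested and BH-adjusted together; the `min_abs_log2fc` cut
  (default 0.25, pseudocount 1) is applied to the *reported* rows only.
  Filtering on effect size before the adjustment selects nulls with inflated
  effects and invalidates the FDR guarantee — measured empirical FDR rises
  from ~0.05 to ~0.5 in a spiked-null experiment — so the fold-change filter
  is deliberately post-hoc. These thresholds are package defaults, not
  literature values.
- **Sex-opposite genes**: genes significant (q ≤ q_max) in both sexes' own
  old-vs-young contrasts with opposite fold-change signs. Requiring
  significance in *both* sexes is the stricter of the two possible readings
  of "opposite alteration pattern"; q_max is exposed.
- **Proportion trends**: one-way fixed-effects ANOVA on per-sample type
  fractions, followed by Dunnett many-to-one comparisons against the
  baseline age (scipy's multivariate-t implementation; the quasi-Monte-Carlo
  CDF evaluation is seeded, and with two groups the procedure reduces to the
  two-sample t-test, verified to 10^-3).

## Cell-cycle scoring

A module score is the per-cell mean expression of a gene set minus the mean
of a pooled control set: genes are binned by global mean expression into 25
equal-frequency bins and 50 controls per set gene are drawn seeded, without
replacement, from the gene's bin. When scoring the S set, the G2M genes are
excluded from the control pool (and vice versa): the two programs co-reside
in the same expression bins, and letting one program serve as controls for
the other cancels the very signal being measured. Phase calls: both scores
≤ 0 → G1, otherwise the larger score's phase (exact ties → S, with a
warning).

Module scores are computed against the background of whatever matrix they
are given. In a heterogeneous tissue the control draw absorbs other types'
identity programs, which biases scores for types that do not carry them;
phase inference for a lineage is therefore best run on that lineage's
subset (the acceptance script scores TAPs within the TAP subset, which
raises correct G1 calls on non-cycling progenitors from ~40% to ~95% in the
synthetic niche).

## Annotation and subclustering

Type assignment is per *cluster*: the score of cluster k for type t is the
mean standardized log expression of t's positive markers minus (equal
weight, configurable) the mean for its negative markers; the cluster takes
the argmax unless it falls below a floor (default 0), in which case it is
"unassigned". Negative markers are what separate NSCs from astrocytes in
both shipped panels.

TAP subclustering is k-means (k=2) on standardized log expression of the
S∪G2M gene set; the subcluster with the higher mean cycle score is
`cycle_active`. NSC subclustering is agglomerative Ward (k=2) on
standardized log expression of the receptor genes present in the curated LR
table; the higher-mean-expression subcluster is `R_H`. k=2 is fixed because
both analyses describe exactly two subpopulations. Whether the receptor
split should use receptor genes only or the whole transcriptome is an open
choice; receptor genes are used here because the split is *defined* by
receptor expression, and the alternative can be obtained by passing a
different gene list.

## The synthetic niche generator

Counts are gamma-Poisson: gene g in cell c has mean
`μ_gc = base_g · 2^(Σ effects) · lib_c`, drawn as NB with per-gene
inverse-dispersion θ (θ = ∞ gives Poisson), then thinned by Bernoulli
dropout with probability `expit(−slope · (ln μ − midpoint))` — low-mean
genes drop out more, producing the zero inflation that the silent-cell
computation relies on. Library size `lib_c` is lognormal with σ = 0.3
(mean-corrected to 1) so normalization is non-trivial.

Planted structure and defaults (one sample per age × sex, ages 2/7/12/19
months, region SVZ):

| structure | default |
|---|---|
| cell types | NSC 120, TAP 100, NB 120, astrocyte 140, oligodendrocyte 120, microglia 100, endothelial 80 per sample |
| age drift | TAP ×0.55/step, NB ×0.70/step, NSC ×0.95, microglia ×1.05 |
| identity programs | 3–4 panel markers at log2FC 3 plus a 30-gene program block at log2FC 2 per type |
| cycle program | 60% of TAPs active at every age; active cells raise S∪G2M by log2 2, their own phase set by one more log2 unit; phases S/G2M split 50/50 |
| receptor program | receptor-high NSC fraction 0.55/0.45/0.35/0.25 across ages, receptor genes ×16 in R_H; receptor base mean 1.0 so R_L detection is low and the state is bimodal |
| per-cell age trends | all curated receptors and Bdnf/Mdk −0.4 log2/step in NSCs; Apoe +0.3/step in astrocytes and TAPs |
| sex-opposite genes | 14 genes (incl. Prdx1) with ±2 log2 at the oldest age, sign by sex |
| silent senders | 35% of niche cells have every curated ligand zeroed |
| LR couplings | Bdnf→Ntrk2 (NSC→NSC) and Mdk→Ptprz1 (astrocyte→NSC) at ρ = 0.8 |
| noise | θ = 2, dropout midpoint 0 / slope 1, library σ 0.3 |

Cell counts per sample are multinomial around the expected proportions, so
realized compositions carry sampling noise. Sender cell *j* and receiver
cell *j* of a sample share a standard-normal latent `u_j`; coupling
multiplies both gene means by `exp(ρσu_j − (ρσ)²/2)`, so ρ = 0 changes
nothing and ρ = 1 gives identical factors on both sides. The truth record
stores per-cell type/subtype/phase/silent labels and the generation-order
index that aligns coupled sender/receiver pairs, plus one row per planted
effect.

Design notes on the defaults: identity programs span ~34 genes because
marker-only (3–4 gene) identities are unrealistically sparse — the standard
HVG/PCA/Leiden pipeline legitimately assumes transcriptome-wide programs.
Cycling cells elevate the whole cycle set because proliferating cells
express cycle genes broadly; the phase-specific extra boost keeps S and G2M
distinguishable. The aging receptor decline is planted both as composition
(the primed receptor-high pool shrinks) and as per-cell drift, matching the
two mechanisms described for the real niches. The silent-sender fraction is
planted directly rather than induced by tuning dropout, because a logistic
dropout cannot be tuned to a sharp target fraction and the planted value is
what recovery is measured against.

**What the generator does not model**: spatial structure, doublets, ambient
RNA, batch/chemistry differences between datasets, transcriptional
continua (all planted states are discrete), and gene–gene correlation
beyond the planted programs. Passing recovery tests therefore shows the
estimators are correct under the assumed noise model, not that the pipeline
is robust to every artifact of real droplet data.

## Pipeline, seeding, determinism

All randomness flows from one global seed, fanned out per stage by SHA-256
hashing of `"{seed}:{stage}"` (mod 2^31), so adding a stage never perturbs
earlier stages. TSV outputs use a fixed float format; a rerun with the same
config and seed is byte-identical (checksums are recorded in the run
report). MatrixMarket files are 1-based on disk and 0-based in memory;
duplicate coordinates and header/table mismatches are hard errors naming
the file.

Degenerate inputs are handled explicitly: all-identical expression in a
subclustering yields a degenerate flag instead of an arbitrary split;
all-zero cells survive normalization as flagged zero rows; empty DEG tables
carry a note; a zero-entropy marginal gives nMI 0.

## Problem sizes

Tests and the acceptance script run the full workflow on the default
synthetic niche (~5,500 cells × 1,000 genes, 8 samples), a scale at which
every planted effect is comfortably detectable and a laptop CPU completes
the whole suite in a few minutes. Monte-Carlo checks (FDR calibration, nMI
coupling ordering, null ANOVA calibration) use 20–100 seeded replicates of
smaller matrices.

## Known limitations

- The communication score uses population means on the partner side; it
  cannot express partner heterogeneity (a few very-high-expressing partner
  cells and a uniform population look identical).
- Cluster-level annotation inherits clustering errors; a mixed cluster gets
  a single label.
- The exact Wilcoxon path enumerates rank splits and is only used for
  groups ≤ 8 cells.
- Dunnett p-values rely on scipy's quasi-Monte-Carlo multivariate-t CDF;
  they are seeded and reproducible but carry ~10^-4-level evaluation noise.
- Phase scoring on a heterogeneous matrix is biased by composition (see
  above); score within lineages.
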