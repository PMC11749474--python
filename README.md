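# nichecomm

Ligand–receptor communication analysis for single-cell RNA-seq data from the
adult neurogenic niches — the subventricular zone (SVZ) and dentate gyrus
(DG) — with a focus on how intercellular signaling to neural stem cells
(NSCs) changes across the mouse lifespan.

Adult neurogenesis declines with age, and a central question is how much of
that decline is driven by the niche: do the cells surrounding NSCs stop
talking to them, or do NSCs stop listening? `nichecomm` implements a
reusable, tested version of the analysis workflow used to study this:

- **QC, normalization and clustering** of 10x-style UMI count matrices
  (MatrixMarket triplets), with per-cell counts-per-million normalization
  (no gene-length term — appropriate for 3'-tag data) and the standard
  variable-gene → PCA → kNN → Leiden pipeline.
- **Marker-based annotation** of clusters, shipping SVZ and DG panels that
  separate NSCs (`Nr2e1`, `Thbs4`, `Igfbp5`, `Notum`; `Thrsp`, `Fabp7`,
  `Hopx` in the DG) from mature astrocytes by the *absence* of `Aqp4`,
  `Tril` and `Grin2c`.
- **Subclustering** of transient amplifying progenitors (TAPs) into
  cell-cycle active/inactive subtypes, and of NSCs into receptor-high
  (NSC-R_H, primed) and receptor-low (NSC-R_L, dormant) subpopulations by
  Ward clustering on curated receptor genes.
- **Cell-cycle phase scoring** (G1/S/G2M) with binned-control module scores.
- **Differential statistics**: Wilcoxon rank-sum DEGs with
  Benjamini–Hochberg FDR (exact enumeration for tiny groups), detection of
  genes with *opposite* aging directions in females and males, and one-way
  ANOVA with Dunnett many-to-one comparisons for cell-proportion trends.
- **Communication scoring** — the core of the package. For a focal cell and
  a curated ligand–receptor (LR) table, the per-cell global communication
  score is

  `S(c) = Σ_p  x_c(g_focal(p)) · mean_partner(g_partner(p))`

  summing over LR pairs *p*: the focal cell's normalized expression of its
  side of the pair times the partner population's mean expression of the
  other side. From these the package derives cumulative-fraction (ECDF)
  curves, the fraction of "silent" cells (score exactly 0), per-age score
  trends, and a differential LR network whose edges are weighted by
  normalized mutual information (nMI) between discretized ligand and
  receptor expression.
- **A synthetic niche generator** (`nichecomm.simulate`) that plants all of
  the structure above — negative-binomial counts with logistic dropout,
  age-declining TAP/NB proportions, a 60/40 cycling TAP split, bimodal
  receptor-high NSCs, sex-opposite aging genes, silent senders, and latent
  ligand–receptor couplings — together with a machine-readable truth record,
  so every stage of the analysis can be tested as a recovery problem.

## Worked example

```python
from nichecomm import default_config, simulate_niche
from nichecomm.preprocess import QCThresholds, qc_filter, normalize
from nichecomm.annotate import subcluster_receptor
from nichecomm.communication import (
    CommunicationConfig, fraction_silent, global_score, scores_by_age,
)
from nichecomm.resources import load_lr_table

cfg = default_config(seed=0)
adata, truth = simulate_niche(cfg)
adata, report = qc_filter(adata, QCThresholds(50, 5000, 0.2, 3))
adata = normalize(adata)

lr = load_lr_table()
types = truth.cells.loc[adata.obs_names, "cell_type"]
nsc = adata.obs_names[(types == "NSC").to_numpy()]
niche = adata.obs_names[(types != "NSC").to_numpy()]

niche_scores = global_score(
    adata, lr, CommunicationConfig("ligand_side", tuple(niche), tuple(nsc))
)
print(f"silent niche senders: {100 * fraction_silent(niche_scores.global_scores):.1f}%")

nsc_mask = (types == "NSC").to_numpy()
for age, t in sorted(scores_by_age(adata, lr, nsc_mask, nsc_mask, "receptor_side").items()):
    print(f"age {age:>2} months: mean NSC global score {t.global_scores.mean():.3e}")

receptors = [g for g in dict.fromkeys(lr["receptor"]) if g in adata.var_names]
sub = subcluster_receptor(adata, nsc, receptors)
print(f"receptor-high NSCs: {100 * (sub.labels == 'R_H').mean():.1f}%")
```

prints

```
silent niche senders: 34.9%
age  2 months: mean NSC global score 6.071e+08
age  7 months: mean NSC global score 3.538e+08
age 12 months: mean NSC global score 2.431e+08
age 19 months: mean NSC global score 1.552e+08
receptor-high NSCs: 41.7%
```

Roughly a third of niche cells send no curated ligand to NSCs at all; the
mean NSC communication score falls monotonically across the four ages
(driven by the shrinking receptor-high pool and per-cell receptor decline
planted by the generator); and the Ward subclustering recovers the planted
~40% receptor-high NSC fraction.

The same workflow runs end to end from one YAML config, writing TSV tables
and a JSON run report with per-stage checksums:

```bash
nichecomm run examples/run_synthetic.yaml
```

Subcommands `simulate`, `qc`, `cluster`, `annotate`, `cellcycle`, `deg`,
`comm` and `validate` expose the individual stages; `nichecomm --help`
lists them.

## Layout

```
src/nichecomm/
  simulate.py        synthetic niche generator + ground truth
  io.py              10x triplet (MatrixMarket) read/write
  preprocess.py      QC, normalization, Leiden clustering
  annotate.py        marker panels, type assignment, subclustering, composition
  cellcycle.py       binned-control module scores, phase calls
  differential.py    Wilcoxon DEGs, BH, sex-opposite genes, ANOVA+Dunnett
  communication.py   LR scores, ECDFs, silent fractions, nMI, networks
  pipeline.py / cli.py   orchestration and command line
  resources/         shipped LR table, marker panels, phase gene lists
```

See `docs/methods.md` for the model, parameter and design documentation.
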