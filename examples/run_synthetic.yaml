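# Full pipeline on the default synthetic niche.
# QC thresholds are scaled to the simulator's 1000-gene panel; for real 10x
# data use min_genes_per_cell ~500 and max_genes_per_cell ~6000.
input:
  simulate: {}
output_dir: scratch/synthetic_run
seed: 0
qc:
  min_genes_per_cell: 50
  max_genes_per_cell: 5000
  max_mito_fraction: 0.2
  min_cells_per_gene: 3
cluster:
  n_top_genes: 2000
  n_comps: 30
  k_neighbors: 15
  resolution: 1.0
annotate:
  panel: svz
differential:
  young_age: 2
  old_age: 19
  cell_type: NSC
  q_max: 0.05
communication:
  lr_table: builtin
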