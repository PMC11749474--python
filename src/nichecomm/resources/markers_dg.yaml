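# Default DG marker panel (mouse gene symbols). DG radial-glia-like NSCs do
# not separate cleanly from astrocytes, so the panel leans on enriched NSC
# markers plus negative astrocyte markers.
region: DG
types:
  NSC:
    positive: [Thrsp, Fabp7, Hopx, Nr2e1]
    negative: [Aqp4, Grin2c]
  Astrocyte:
    positive: [Aqp4, Grin2c, Slc1a3]
    negative: []
  IPC:
    positive: [Ascl1, Eomes, Neurod4]
    negative: []
  NB:
    positive: [Dcx, Stmn2, Sox11]
    negative: []
  Oligodendrocyte:
    positive: [Plp1, Mbp, Mog]
    negative: []
  Microglia:
    positive: [C1qa, Cx3cr1, Csf1r]
    negative: []
  Endothelial:
    positive: [Cldn5, Pecam1, Flt1]
    negative: []
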