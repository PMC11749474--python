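# Default SVZ marker panel (mouse gene symbols).
# NSCs are called from stem-cell markers and distinguished from mature
# astrocytes by the absence of Aqp4/Tril/Grin2c, which NSCs do not express.
region: SVZ
types:
  NSC:
    positive: [Nr2e1, Thbs4, Igfbp5, Notum]
    negative: [Aqp4, Tril, Grin2c]
  Astrocyte:
    positive: [Aqp4, Tril, Grin2c, Slc1a3]
    negative: []
  TAP:
    positive: [Ascl1, Dlx2, Egfr]
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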