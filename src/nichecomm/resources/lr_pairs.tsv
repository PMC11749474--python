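ligand	receptor	source
Bdnf	Ntrk2	curated
Ntf5	Ntrk2	curated
Mdk	Ptprz1	curated
Ptn	Ptprz1	curated
Dll1	Notch1	curated
Jag1	Notch1	curated
Dll1	Notch2	curated
Igf1	Igf1r	curated
Igf2	Igf1r	curated
Tgfb1	Tgfbr1	curated
Tgfb2	Tgfbr2	curated
Bmp4	Bmpr1a	curated
Fgf2	Fgfr1	curated
Fgf1	Fgfr2	curated
Vegfa	Nrp1	curated
Apoe	Lrp1	curated
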