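Mcm2
Mcm5
Mcm6
Pcna
Rrm2
Fen1
Gins2
Cdc6
Uhrf1
Dtl
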