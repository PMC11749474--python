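Ube2c
Hmgb2
Mki67
Ccnb1
Ccnb2
Top2a
Cdk1
Birc5
Cenpa
Bub1
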