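layer,thickness_cm,ll,dul,sat
1,15,0.18,0.30,0.42
2,15,0.18,0.30,0.42
3,20,0.19,0.31,0.43
4,25,0.20,0.32,0.44
5,25,0.20,0.32,0.44
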