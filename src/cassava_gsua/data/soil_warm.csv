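layer,thickness_cm,ll,dul,sat
1,15,0.12,0.24,0.40
2,15,0.12,0.24,0.40
3,20,0.13,0.25,0.41
4,25,0.14,0.26,0.42
5,25,0.15,0.27,0.43
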