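category,n_malignant,n_benign_normal
4,58,2
3,3,24
2,2,11
1,0,26
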