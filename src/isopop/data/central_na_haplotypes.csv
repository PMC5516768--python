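haplotype,frequency
J,0.26
K,0.044
L,0.39
M,0.044
N,0.26
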