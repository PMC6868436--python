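>SYN0001.1 ctcf_like_synthetic
A [  7   7   7   7   7  79   7   7  79   7   7   7   7   7   7   7   7   7  79 ]
C [  7   7   7  79  79   7  79  79   7   7   7   7   7   7  79   7  79   7   7 ]
G [  7  79  79   7   7   7   7   7   7  79  79  79  79  79   7  79   7   7   7 ]
T [ 79   7   7   7   7   7   7   7   7   7   7   7   7   7   7   7   7  79   7 ]
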