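category	targets
0	259
1	38
2	305
3	31
4	265
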