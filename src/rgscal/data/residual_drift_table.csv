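single_block_cm,three_block_cm
0.15,0.00
0.21,0.02
0.22,0.02
0.27,-0.02
0.27,0.03
0.28,0.03
0.29,0.03
0.33,-0.03
0.34,0.07
0.60,0.08
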