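AOI1,AOI2,AOI3,AOI4,AOI5,AOI6
0.01,0.088,0.353,0.147,0.088,0.314
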