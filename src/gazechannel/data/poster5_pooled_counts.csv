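,AOI1,AOI2,AOI3,AOI4
AOI1,71,23,1,0
AOI2,19,149,45,0
AOI3,5,43,690,29
AOI4,1,0,31,63
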