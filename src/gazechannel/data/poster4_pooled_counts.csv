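,AOI1,AOI2,AOI3,AOI4
AOI1,50,32,2,1
AOI2,31,253,52,0
AOI3,4,50,636,21
AOI4,0,1,21,38
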