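,AOI1,AOI2,AOI3,AOI4
AOI1,56,32,1,0
AOI2,25,159,49,0
AOI3,8,38,700,38
AOI4,1,4,36,52
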