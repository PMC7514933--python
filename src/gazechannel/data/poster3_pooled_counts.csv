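,AOI1,AOI2,AOI3
AOI1,241,54,1
AOI2,45,537,50
AOI3,10,45,269
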