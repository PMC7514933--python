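,AOI1,AOI2,AOI3
AOI1,419,25,0
AOI2,24,518,19
AOI3,2,19,64
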