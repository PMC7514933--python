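,AOI1,AOI2,AOI3
AOI1,337,42,4
AOI2,41,138,42
AOI3,6,41,506
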