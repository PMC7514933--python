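,AOI1,AOI2,AOI3,AOI4,AOI5,AOI6
AOI1,0.75,0.125,0.0,0.0,0.125,0.0
AOI2,0.0,0.818,0.182,0.0,0.0,0.0
AOI3,0.0,0.125,0.813,0.063,0.0,0.0
AOI4,0.0,0.0,0.0,0.75,0.0,0.25
AOI5,0.0,0.0,0.0,0.0,0.894,0.106
AOI6,0.026,0.0,0.0,0.026,0.18,0.769
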