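,AOI1,AOI2,AOI3,AOI4,AOI5,AOI6
AOI1,0.0,1.0,0.0,0.0,0.0,0.0
AOI2,0.111,0.333,0.556,0.0,0.0,0.0
AOI3,0.0,0.111,0.806,0.083,0.0,0.0
AOI4,0.0,0.0,0.133,0.8,0.067,0.0
AOI5,0.0,0.0,0.0,0.0,0.778,0.222
AOI6,0.0,0.031,0.0,0.0,0.031,0.934
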