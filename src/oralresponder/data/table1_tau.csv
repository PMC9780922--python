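phase,P1,P2,P3,P4,P5,P6,P7,P8,P9,P10,P11
II,0.014,0.008,0.014,0.011,0.014,0.017,0.011,0.019,0.009,0.016,0.020
III,0.014,0.009,0.010,0.014,0.016,0.021,0.024,0.018,0.016,0.020,0.024
IV,0.012,0.011,0.019,0.015,0.012,0.017,0.015,0.020,0.016,0.018,0.021
V,0.007,0.007,0.022,0.013,0.013,0.023,0.015,0.026,0.015,0.017,0.026
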