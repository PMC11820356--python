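participant,sliding_bpm,stepped_bpm
P1,4.34,4.5
P2,4.92,5.0
P3,5.27,5.5
P4,5.46,5.5
P5,4.77,4.5
P6,5.07,4.5
P7,5.42,6.0
P8,4.55,4.5
P9,4.34,4.5
P10,4.32,4.5
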