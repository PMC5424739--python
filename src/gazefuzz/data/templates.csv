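1,0.5,0,0.08571428571,0.1714285714,0.2571428571,0.3428571429,0.4285714286,0.5142857143,0.6
1,0.75,0.5,0.25,0,0.12,0.24,0.36,0.48,0.6
1,0.8333333333,0.6666666667,0.5,0.3333333333,0.1666666667,0,0.2,0.4,0.6
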