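factor_value,risk_percent
6.8,14.5
6.95,3
7.85,20
7.95,3.8
8,14
8.95,7.1
9.2,27
9.5,20
9.9,27
9.95,7.9
10.5,9.9
10.55,28
11.7,51
12,32
13,32
13.7,40
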