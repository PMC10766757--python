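grid_value,rotation,choice_pct
7,45,10.0
7,90,5.0
8,90,2.5
8,270,2.5
9,180,2.5
10,225,2.5
12,45,2.5
12,135,10.0
12,180,2.5
13,270,47.5
14,90,2.5
14,180,2.5
17,135,7.5
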