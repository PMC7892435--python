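marker	alleles
D1S212	20
D1S2659	11
D1S218	24/25
D1S2790	20
D1S1165	13
D1S2815	18
D1S196	12
D1S460	7
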