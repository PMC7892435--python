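marker	delta
D1S212	0.326
D1S2659	0.628
D1S218	0.945
D1S2790	0.899
D1S1165	0.741
D1S2815	0.731
D1S196	0.470
D1S460	0.086
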