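marker	side	dist_cM	repeat_unit	mu
D1S2790	proximal	1.00	2	5.6e-4
D1S1165	proximal	2.43	4	2.1e-3
D1S2815	proximal	2.53	2	5.6e-4
D1S196	proximal	7.35	2	5.6e-4
D1S460	proximal	54.8	2	5.6e-4
D1S218	distal	0.73	2	5.6e-4
D1S2659	distal	3.27	2	5.6e-4
D1S212	distal	4.92	2	5.6e-4
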