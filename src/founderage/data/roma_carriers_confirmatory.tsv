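id	gender	age	genotype	event_history	risk_factors
1	male	24	heterozygote	no	obesity
2	male	27	heterozygote	no	none
3	female	28	homozygote	no	none
4	female	35	heterozygote	no	obesity
5	female	42	heterozygote	no	obesity,HLP
6	female	53	heterozygote	MI	obesity,DM,HT
7	female	54	heterozygote	no	none
8	male	56	heterozygote	no	obesity,HT,HLP
9	female	57	heterozygote	no	DM,HT
10	female	58	heterozygote	MI	obesity,HT,HLP
11	female	60	heterozygote	no	obesity,DM,HT
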