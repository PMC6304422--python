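chrom	start	end	circ_id	gene	jurkat	shsy5y
3	119219542	119222868	hsa_circ_0001329	TIMMDC1	x	x
3	119219542	119232566	hsa_circ_0006884	TIMMDC1	x	.
3	119219542	119236162	hsa_circ_0066874	TIMMDC1	x	.
4	103610731	103651893	hsa_circ_0001431	MANBA	x	.
4	103635595	103651893	hsa_circ_0142051	MANBA	x	.
4	106155054	106158508	hsa_circ_0070562	TET2	x	x
7	50358644	50367353	hsa_circ_0001708	IKZF1	x	.
7	50358644	50459561	novel	IKZF1	x	.
7	50444231	50459561	novel	IKZF1	x	.
16	11063018	11076848	hsa_circ_0004179	CLEC16A	x	.
16	11114050	11145498	hsa_circ_0002086	CLEC16A	x	.
16	11114050	11154879	hsa_circ_0000672	CLEC16A	x	.
16	11114050	11220003	hsa_circ_0007846	CLEC16A	x	x
17	57808782	57816308	hsa_circ_0006508	VMP1	x	x
17	57808782	57851246	hsa_circ_0005077	VMP1	x	.
22	22153301	22162135	hsa_circ_0004872	MAPK1	x	.
22	22160139	22162135	hsa_circ_0008870	MAPK1	x	.
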