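step_index	substrate	product	core_enzymes	branch_enzymes
1	glc	g6p	HK2
2	g6p	f6p	GPI	G6PD;PGM1
3	f6p	fbp	PFKP	GFPT1
4	fbp	dhap	ALDOA
5	dhap	gap	TPI1	GPD1
6	gap	bpg13	GAPDH
7	bpg13	pg3	PGK1
8	pg3	pg2	PGAM1	PHGDH
9	pg2	pep	ENO1
10	pep	pyr	PKM
11	pyr	lac	LDHA	GPT;PDHA1
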