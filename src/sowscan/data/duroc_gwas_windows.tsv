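chrom	start_bp	end_bp	pct_variance
2	4239252	5222613	1.57
2	145012848	146011865	1.01
3	3981003	4980011	1.16
4	20774634	21762434	1.07
4	104642633	105640667	1.13
11	25254733	26232874	1.18
12	54066400	55065792	1.10
12	56619955	57608007	1.30
13	3171064	4162557	1.35
13	10788202	11761268	2.27
14	13059455	14032461	2.14
15	55188321	56161595	1.28
15	57551770	58532159	1.29
15	131996123	132969736	1.09
16	77028962	78013471	2.55
17	17325007	18300615	1.04
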