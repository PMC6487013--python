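chrom	chrom_length_bp	n_cnvr	cnvr_length_bp
1	315321322	49	12420297
2	162569375	33	17317379
3	144787322	30	12626965
4	143465943	15	10565509
5	111506441	17	9232945
6	157765593	22	12493722
7	134764511	26	10659114
8	148491826	36	10789394
9	153670197	19	12793931
10	79102373	16	8515041
11	87690581	22	14058242
12	63588571	25	8687209
13	218635234	24	11779507
14	153851969	27	9624904
15	157681621	26	23006893
16	86898991	12	5426107
17	69701581	10	3519539
18	61220071	16	3522196
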