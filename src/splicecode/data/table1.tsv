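rank	motif	count
0	ALL	215155
1	gugagu_ag	30585
2	guaag_ag	29538
3	guaagu_ag	28972
4	gugag_ag	26627
5	guaa_ag	22188
6	gua_ag	20040
7	guagg_ag	12474
8	guaugu_ag	6312
9	guaug_ag	5552
10	guggg_cag	5168
11	gu_ag	4901
12	guga_ag	3332
13	gucagu_ag	2439
14	gugcg_cag	1904
15	gucag_ag	1650
16	gugugu_ag	1421
17	guuagu_ag	1415
18	guuugu_ag	1113
19	gcaagu_ag	967
20	guuggu_ag	929
21	gugggu_ag	918
22	gugug_ag	912
23	guggg_ag	719
24	gucugu_ag	450
25	gucug_ag	371
26	gugcgu_ag	311
27	gcaag_ag	301
28	gugcg_ag	255
29	guauccuuu_ag	250
30	gc_ag	230
31	gucgg_cag	202
32	guca_ag	198
33	guccg_ag	162
34	gcagg_ag	153
35	guucgu_ag	147
36	guauccuu_ag	144
37	auauccuu_ac	124
38	gua_ugguuucag	118
39	guaag_uguucag	117
40	gu_ugguuuuag	113
41	gcaug_ag	112
42	gu_uuugagacag	109
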