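scaffold	length_mb	n_snps
Scaffold1	37.08	503
Scaffold2	29.80	406
Scaffold3	24.17	456
Scaffold4	24.19	311
Scaffold5	23.24	376
Scaffold6	20.31	758
Scaffold7	25.40	282
Scaffold8	26.72	1234
Scaffold9	15.31	139
Scaffold10	22.50	1320
Scaffold11	13.42	141
Scaffold12	13.10	284
Scaffold13	13.34	50
Scaffold14	13.56	188
Scaffold16	16.70	278
Scaffold17	13.29	56
Scaffold18	12.91	329
Scaffold19	12.66	173
Scaffold20	13.35	104
Scaffold21	12.91	176
Scaffold22	13.11	144
Scaffold23	16.07	79
Scaffold24	11.92	50
Scaffold25	23.23	203
Scaffold26	12.29	226
Scaffold27	10.49	150
Scaffold28	12.49	961
Scaffold29	10.52	126
Scaffold30	16.12	68
Scaffold31	12.85	145
Scaffold32	11.01	116
Scaffold33	10.69	56
Scaffold34	10.66	89
Scaffold36	18.43	1211
Scaffold41	16.55	219
Scaffold45	11.91	85
Scaffold47	10.04	147
Scaffold49	10.33	104
Scaffold64	15.38	203
Scaffold66	11.16	52
Scaffold68	10.66	90
Scaffold70	12.54	215
Scaffold72	10.47	379
Scaffold73	13.59	237
Scaffold93	12.16	189
Scaffold99	10.59	213
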