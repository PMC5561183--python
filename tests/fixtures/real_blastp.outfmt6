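protA	protA	100.000	138	0	0	1	138	1	138	1.24e-96	262
protA	protB	93.478	138	9	0	1	138	1	138	2.09e-82	226
protA	protC	76.336	131	30	1	9	138	22	152	4.87e-51	147
protB	protB	100.000	138	0	0	1	138	1	138	6.06e-97	263
protB	protA	93.478	138	9	0	1	138	1	138	1.75e-82	226
protB	protC	75.573	131	31	1	9	138	22	152	1.33e-50	146
protC	protC	100.000	152	0	0	1	152	1	152	2.75e-106	288
protC	protA	76.119	134	31	1	19	152	6	138	3.41e-61	173
protC	protA	58.333	12	5	0	8	19	107	118	0.36	16.9
protC	protB	75.373	134	32	1	19	152	6	138	9.33e-61	172
protC	protB	50.000	16	8	0	4	19	103	118	0.12	18.1
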