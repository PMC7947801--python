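qtl	n_alleles	neg_lg_p	r2_pct
qNdvi-01-1	2	3.80	1.28
qNdvi-01-2	2	1.82	0.53
qNdvi-01-3	3	4.06	1.69
qNdvi-01-4	2	8.42	3.18
qNdvi-01-5	2	1.72	0.49
qNdvi-02-1	4	8.33	3.84
qNdvi-03-1	2	2.85	0.92
qNdvi-05-1	2	1.96	0.58
qNdvi-05-2	2	1.46	0.40
qNdvi-05-3	4	7.73	3.57
qNdvi-05-4	4	3.80	1.82
qNdvi-05-5	2	1.74	0.50
qNdvi-05-6	2	1.55	0.43
qNdvi-06-1	2	6.24	2.27
qNdvi-06-2	2	2.44	0.76
qNdvi-06-3	2	2.58	0.81
qNdvi-08-1	2	2.73	0.87
qNdvi-08-2	2	3.96	1.35
qNdvi-08-3	2	3.36	1.11
qNdvi-10-1	3	1.78	0.74
qNdvi-10-2	2	5.58	2.00
qNdvi-11-1	2	2.58	0.81
qNdvi-11-2	2	5.16	1.83
qNdvi-11-3	3	2.18	0.90
qNdvi-13-1	3	2.57	1.06
qNdvi-13-2	2	1.98	0.59
qNdvi-13-3	2	1.37	0.37
qNdvi-14-1	2	1.63	0.46
qNdvi-14-2	3	7.06	2.97
qNdvi-15-1	3	1.89	0.78
qNdvi-15-2	3	6.27	2.63
qNdvi-15-3	2	3.88	1.32
qNdvi-15-4	2	2.06	0.62
qNdvi-16-1	2	1.93	0.57
qNdvi-17-1	2	2.63	0.83
qNdvi-18-1	2	4.76	1.67
qNdvi-19-1	2	3.53	1.18
qNdvi-19-2	2	2.17	0.66
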