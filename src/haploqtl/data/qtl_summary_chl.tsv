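qtl	n_alleles	neg_lg_p	r2_pct
qChl-01-1	3	7.32	2.97
qChl-02-1	2	8.17	2.96
qChl-03-1	2	3.66	1.18
qChl-05-1	2	2.98	0.93
qChl-05-2	2	1.96	0.56
qChl-06-1	2	2.37	0.70
qChl-06-2	3	6.74	2.73
qChl-07-1	3	3.01	1.20
qChl-07-2	3	6.35	2.57
qChl-08-1	2	1.84	0.51
qChl-08-2	3	12.97	5.38
qChl-08-3	3	3.74	1.50
qChl-08-4	2	1.46	0.38
qChl-09-1	2	2.41	0.72
qChl-10-1	3	12.42	5.14
qChl-11-1	3	5.90	2.38
qChl-13-1	2	2.59	0.78
qChl-13-2	2	3.93	1.29
qChl-14-1	2	1.91	0.54
qChl-14-2	2	2.77	0.85
qChl-15-1	2	1.68	0.46
qChl-15-2	2	2.50	0.75
qChl-15-3	2	1.98	0.56
qChl-16-1	2	4.24	1.40
qChl-16-2	2	3.66	1.18
qChl-16-3	2	3.78	1.23
qChl-17-1	2	2.24	0.66
qChl-17-2	2	5.88	2.04
qChl-18-1	4	2.65	1.26
qChl-18-2	4	3.58	1.66
qChl-19-1	6	4.25	2.36
qChl-20-1	4	5.59	2.52
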