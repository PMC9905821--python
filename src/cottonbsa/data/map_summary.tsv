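chrom	n_markers	length_cM	avg_interval_cM	largest_gap_cM	collinearity
A1	165	157.86	0.96	10.09	-1.00
A2	30	161.10	5.56	28.19	-1.00
A3	487	150.74	0.31	9.25	-1.00
A4	514	164.16	0.32	10.77	-0.99
A5	488	168.17	0.35	3.43	-1.00
A6	152	162.13	1.07	14.63	-1.00
A7	583	162.98	0.28	9.13	-0.90
A8	414	156.02	0.38	7.74	-0.84
A9	624	178.90	0.29	7.61	-1.00
A10	415	161.14	0.39	8.91	-0.99
A11	338	161.48	0.48	6.49	-1.00
A12	270	160.78	0.60	13.61	-1.00
A13	1115	172.27	0.15	2.51	-0.82
D1	752	159.88	0.21	6.18	-0.68
D2	311	161.47	0.52	8.92	-1.00
D3	83	166.45	2.03	21.48	-1.00
D4	82	161.89	2.00	19.21	-1.00
D5	1318	162.01	0.12	2.60	-1.00
D6	241	170.41	0.71	13.22	-1.00
D7	359	157.39	0.44	25.66	-1.00
D8	900	155.69	0.17	2.66	-0.97
D9	349	160.44	0.46	8.78	-1.00
D10	743	161.22	0.22	9.77	-0.98
D11	236	151.28	0.64	7.66	-1.00
D12	323	161.79	0.50	17.07	-1.00
D13	196	154.46	0.79	7.64	-1.00
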