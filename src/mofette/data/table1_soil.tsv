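site	layer	pH	HCl	N_pct	C_pct	CN
3	Sup	7.32	Strong	0.52	14.23	27.61
3	Sub	7.31	Strong	0.25	10.98	44.03
4	Sup	7.31	Strong	0.75	11.69	15.50
4	Sub	7.60	Strong	0.29	10.14	35.46
5	Sub	7.14	Strong	0.08	11.89	149.02
6	Sub	6.68	Strong	0.49	12.88	26.33
7	Sup	4.68	None	1.46	15.11	10.32
7	Sub	5.76	None	0.16	2.31	14.54
7	Deep	5.83	None	0.25	4.87	19.41
8	Sup	5.36	None	1.38	16.61	12.05
8	Sub	5.76	None	0.61	7.77	12.68
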