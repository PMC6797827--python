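site	depth_cm	CO2	H2S	N2	O2	Ar	CH4	C2H6	d13C_CO2	d13C_CH4
#units:		mmol/mol	mmol/mol	mmol/mol	mmol/mol	mmol/mol	umol/mol	umol/mol	permil	permil
3	10	43	<0.05	799	147	11	0.5	0.5	-10.79	nd
3	20	67	<0.05	788	133	11	1.4	1.2	-10.11	nd
3	30	101	<0.05	805	84	11	1.9	2	-11.5	nd
3	40	143	<0.05	802	45	10	3	2.7	-8.5	nd
3	50	183	<0.05	783	24	11	5	2.9	-7.82	nd
4	10	9	<0.05	798	183	10	<0.1	<0.1	nd	nd
4	20	11	<0.05	812	166	11	<0.1	<0.1	-10.45	nd
4	30	13	<0.05	820	155	12	<0.1	<0.1	nd	nd
4	40	17	<0.05	821	149	13	0.5	0.5	-11.87	nd
4	50	18	<0.05	821	148	13	1.1	1	nd	nd
5	10	64	<0.05	820	106	10	1.6	2	-8.64	nd
5	20	96	<0.05	804	89	12	2.4	2	-7.64	nd
5	30	137	<0.05	814	38	11	5	4.4	-7.65	nd
5	40	173	<0.05	791	25	12	11	5.9	-7.45	nd
5	50	226	<0.05	744	19	12	16	6.1	-7.13	nd
6	10	397	<0.05	568	27	8.4	21	9	-7.1	nd
6	20	404	<0.05	567	20	8.9	26	9.5	-7.83	-23.3
6	30	373	<0.05	601	12	14	28	11	-8.05	nd
6	40	670	<0.05	322	<0.5	8.3	18	6.3	-7.2	nd
6	50	730	0.1	264	<0.5	6.5	19	5.9	-8.14	nd
8	10	805	0.11	190	<0.5	4.9	41	4.5	-6.06	nd
8	20	807	0.18	188	<0.5	4.6	41	4.2	-6.38	-31.7
BP		983	0.25	16	<0.5	1.1	125	7.9	-6.41	-38.5
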