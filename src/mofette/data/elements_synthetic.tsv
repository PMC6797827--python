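# SYNTHETIC element table (mg/kg dry soil). The study's supplementary element
# data are not printed in the main text; these values are constructed so that
# the site-7 change relative to the mean of sites 3 and 4 reproduces the
# reported structure: Ca -93%, total P +604%, K +113%, with losses of Mg and
# Li and gains of Cu, Pb, Fe and Al.
site	Ca	Mg	Li	P	K	Cu	Pb	Fe	Al
3	95000	9000	18	400	4500	18	9	18000	28000
4	105000	11000	22	600	5500	22	11	22000	32000
7	7000	4000	8	3520	10650	30	14	30000	39000
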