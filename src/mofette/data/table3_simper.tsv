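otu_id	phylum	taxon	pct_con	pct_cum
OTU_1	Thaumarchaeota	Nitrosospheraceae (Family)	2.35	2.35
OTU_3	Thaumarchaeota	Cenarchaeales (SAGMA-X) (Order)	1.69	4.04
OTU_19	Deltaproteobacteria	Syntrophobacteraceae (Family)	1.27	5.31
OTU_12	Chloroflexi	Thermogemmatisporaceae (Family)	1.01	6.33
OTU_6	Gammaproteobacteria	Xanthomonadaceae (Family)	0.94	7.27
OTU_13	Verrucomicrobia	Chthoniobacteraceae (Family)	0.92	8.19
OTU_5	WPS-2		0.72	8.91
OTU_16	Verrucomicrobia	Chthoniobacteraceae (Family)	0.68	9.59
OTU_7	Alphaproteobacteria	Rhizobiales (Order)	0.66	10.24
OTU_68	Acidobacteria	Acidobacteria-6 (Class)	0.63	10.88
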