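trait	gene	snp	effect_allele	eaf	beta	p	ceu_freq	ref_snp	ref_effect_allele	ref_beta	ref_study
MCV	HBS1L/MYB	rs4895441	G	0.27	0.854	5.03e-13	0.22	rs4895441	A	-0.008	GanEtAl
MCV	HBS1L/MYB	rs4895441	G	0.27	0.854	5.03e-13	0.22	rs9402686	A	0.818	SorEtAl
RBC	HBS1L/MYB	rs4895441	G	0.27	-0.081	2.46e-13	0.22	rs9483788	T	0.014	GanEtAl
MCV	TMPRSS6	rs855791	A	0.44	-0.620	5.41e-09	0.39	rs855791	A	-0.127	BenEtAl
MCV	TMPRSS6	rs855791	A	0.44	-0.620	5.41e-09	0.39	rs2413450	A	-0.005	GanEtAl
MCH	TMPRSS6	rs855791	A	0.44	-0.289	1.10e-12	0.39	rs855791	A	-0.330	ChaEtAl
MCH	TMPRSS6	rs855791	A	0.44	-0.289	1.10e-12	0.39	rs5756506	C	0.137	SorEtAl
MCV	HFE	rs1800562	A	0.06	1.087	5.84e-07	0.04	rs1800562	A	0.222	BenEtAl
MCV	HFE	rs1800562	A	0.06	1.087	5.84e-07	0.04	rs1800562	A	0.012	GanEtAl
MCV	HFE	rs1800562	A	0.06	1.087	5.84e-07	0.04	rs1800562	A	1.408	SorEtAl
MCV	HFE	rs1800562	A	0.06	1.087	5.84e-07	0.04	rs198846	A	0.820	ChaEtAl
MCH	HFE	rs1800562	A	0.06	0.494	2.76e-09	0.04	rs198846	A	0.370	ChaEtAl
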