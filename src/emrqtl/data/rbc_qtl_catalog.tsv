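trait	chrom_band	snp	bp	minor_allele	maf	gene	beta	se	r2_pct	p
RBC	6q23.3	rs7775698	135460328	T	0.26	HBS1L/MYB	-0.086	0.011	1.248	1.11e-14
RBC	6q23.3	rs4895441	135468266	G	0.27	HBS1L/MYB	-0.081	0.011	1.105	2.46e-13
RBC	6q23.3	rs9376092	135468837	A	0.27	HBS1L/MYB	-0.081	0.011	1.102	2.85e-13
RBC	6q23.3	rs9494145	135474245	C	0.24	HBS1L/MYB	-0.080	0.012	1.069	7.18e-12
RBC	6q23.3	rs6569992	135493845	A	0.20	HBS1L/MYB	-0.073	0.012	0.709	5.57e-09
MCV	6q23.3	rs7775698	135460328	T	0.26	HBS1L/MYB	0.919	0.119	1.963	1.37e-14
MCV	6q23.3	rs4895441	135468266	G	0.27	HBS1L/MYB	0.854	0.118	1.723	5.03e-13
MCV	6q23.3	rs9376092	135468837	A	0.27	HBS1L/MYB	0.846	0.118	1.695	7.94e-13
MCV	6q23.3	rs9494145	135474245	C	0.24	HBS1L/MYB	0.982	0.124	2.022	2.82e-15
MCV	6q23.3	rs6569992	135493845	A	0.20	HBS1L/MYB	0.844	0.133	1.285	2.50e-10
MCV	6q23.3	rs17064262	135507167	C	0.19	HBS1L/MYB	0.750	0.136	0.977	3.49e-08
MCV	22q12.3	rs855791	35792882	A	0.44	TMPRSS6	-0.620	0.106	1.011	5.41e-09
MCH	6q23.3	rs7775698	135460328	T	0.26	HBS1L/MYB	0.370	0.045	2.233	5.17e-16
MCH	6q23.3	rs4895441	135468266	G	0.27	HBS1L/MYB	0.343	0.045	1.960	3.12e-14
MCH	6q23.3	rs9376092	135468837	A	0.27	HBS1L/MYB	0.340	0.045	1.931	4.94e-14
MCH	6q23.3	rs9494145	135474245	C	0.24	HBS1L/MYB	0.380	0.047	2.114	1.36e-15
MCH	6q23.3	rs6569992	135493845	A	0.20	HBS1L/MYB	0.333	0.051	1.413	7.05e-11
MCH	6q23.3	rs17064262	135507167	C	0.19	HBS1L/MYB	0.295	0.052	1.069	1.42e-08
MCH	6p22.2	rs17342717	25929749	T	0.10	SLC17A1	0.377	0.069	0.985	4.66e-08
MCH	6p22.1	rs1800562	26201120	A	0.06	HFE	0.494	0.083	1.137	2.76e-09
MCH	22q12.3	rs855791	35792882	A	0.44	TMPRSS6	-0.289	0.040	1.525	1.10e-12
MCH	22q12.3	rs5756504	35797216	T	0.36	TMPRSS6	0.234	0.042	0.949	3.73e-08
MCH	22q12.3	rs4820268	35799537	G	0.47	TMPRSS6	-0.267	0.040	1.371	2.41e-11
MCHC	22q12.3	rs855791	35792882	A	0.44	TMPRSS6	-0.084	0.013	1.345	2.40e-11
MCHC	22q12.3	rs4820268	35799537	G	0.47	TMPRSS6	-0.088	0.012	1.582	1.13e-12
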