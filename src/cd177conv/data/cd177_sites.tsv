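# schema: cd177conv/sites/1
site_id	g_pos	c_pos	exon	ref_base	var_base	site_class	aa_change	rsid	carrier_prevalence	hg38_pos	db_note
g.49	49	9	1	G	C	SNP	A3A	rs45441892	23/39	43353721	A3P
g.220	220	92	2	A	T	SNP	H31L	rs45553433	2/39	43353892	H31L
g.242	242	114	2	G	A	SNP	L38L	rs45571738	7/39	43353914	L38L
g.1991	1991	381	4	C	G	PSV	P127P	novel	39/39	43355663	P128A
g.2368	2368	551	5	G	T	PSV	G184V	rs12981714	38/39	43356040	db orientation T->G V184G
g.2427	2427	610	5	A	G	PSV	N204D	rs12980412	38/39	43356099	db orientation G->A D204N
g.2431	2431	614	5	G	T	PSV	R205M	rs12981771	38/39	43356103	db orientation T->G M205R
g.6683	6683	710	6	T	C	SNP	M237T	rs57802244	1/39	43360355	M237T
g.6724	6724	751	6	C	A	SNP	L251I	rs10425835	27/39	43360396	L251I
g.7492	7492	782	7	G	C	PSV	G261A	novel	39/39	43361164	G261A
g.7496	7496	786	7	A	C	PSV	T262T	novel	39/39	43361168	T262T
g.7497	7497	787	7	A	T	PSV	K263X	novel	39/39	43361169	K263X
g.7500	7500	790	7	G	A	PSV	G264S	rs200145410	39/39	43361172	G264S
g.7501	7501	791	7	G	T	SNP	G264V	rs200006364	10/39	43361173	G264V
g.7509	7509	799	7	A	G	PSV	T267A	rs201266439	39/39	43361181	printed cDNA pos 798
g.7968	7968	1022	8	G	A	SNP	S341N	rs17856829	15/39	43361540	A348T
g.8625	8625	1281	9	G	A	SNP	G427G	rs78718189	4/39	43362297	G431R
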