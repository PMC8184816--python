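snp_id	major	minor	maf	chrom	pos	gene	beta	p_adj
rs2182598	A	T	0.0119	1	109766687	SARS	0.39	1.0E-02
rs12081406	A	G	0.01786	1	109778391	SARS	0.45	6.1E-02
rs2808631	T	C	0.02976	1	159682036	CRP	-0.62	4.0E-03
rs10925263	A	G	0.1131	1	237063748	MTR	0.31	5.5E-02
rs138583897	T	G	0.0119	2	170061860	LRP2	0.91	7.1E-03
rs74791051	A	G	0.01786	2	170085774	LRP2	-0.44	2.2E-03
rs144147038	C	T	0.0119	2	170145661	LRP2	-0.49	1.9E-02
rs1800249	C	A	0.04762	3	133464794	TF	0.42	4.7E-02
rs7633232	G	C	0.02083	3	133475614	TF	0.52	6.1E-02
rs78536844	G	A	0.01488	3	158388161	LXN	0.79	9.0E-02
rs1220841	G	A	0.03869	4	70795699	CSN1S1	0.49	5.4E-03
rs1529038	A	G	0.1637	4	70795920	CSN1S1	-0.33	1.5E-02
rs10489132	A	G	0.03571	4	99950417	METAP1	-0.41	5.5E-02
rs1304811491	A	G	0.0119	5	178768430	ADAMTS2	0.55	5.5E-02
rs141206548	T	C	0.01488	6	70408871	LMBRD1	-0.54	4.6E-02
rs116157801	G	A	0.02381	9	130569812	FPGS	0.40	8.2E-02
rs144213212	A	G	0.05357	9	131118554	SLC27A4	0.30	9.1E-02
rs117412228	G	A	0.02083	10	17046009	CUBN	0.51	3.5E-02
rs11254386	G	C	0.0119	10	17171907	CUBN	0.27	8.9E-03
rs116286548	A	G	0.0119	11	59630345	TCN1	-0.77	4.7E-02
rs28989521	A	G	0.04167	12	6898084	CD4	-0.44	4.0E-02
rs72648013	G	A	0.02381	12	110025617	MVK	0.45	5.4E-03
rs41288280	G	A	0.0119	13	25272833	ATP12A	-0.91	1.3E-03
rs721922	A	G	0.1339	13	100462812	CLYBL	-0.30	3.8E-02
rs148126159	G	A	0.01488	14	74752605	ABCD4	0.71	4.2E-06
rs79752143	G	A	0.02679	16	23606959	NDUFAB1	0.55	9.8E-04
rs147671744	G	A	0.02083	17	17460540	PEMT	-0.46	6.1E-02
rs8083543	C	T	0.02083	18	74726712	MBP	0.43	6.1E-02
rs116910911	G	A	0.02083	18	74768653	MBP	0.46	4.7E-02
rs75243301	A	G	0.0119	19	5841156	FUT6	-0.32	4.4E-02
rs6090388	G	A	0.381	20	61336359	NTSR1	0.20	7.3E-02
rs34864360	C	T	0.01488	20	61386225	NTSR1	0.37	1.1E-02
rs45613333	G	A	0.0119	20	61391514	NTSR1	-0.67	4.3E-04
rs111386779	C	T	0.02083	21	44473450	CBS	0.44	1.4E-02
rs150181241	C	T	0.01488	21	44483279	CBS	-0.47	6.1E-02
brz:22:31023366	A	G	0.0119	22	31023366	TCN2	-1.02	2.9E-04
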