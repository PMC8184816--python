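1	1195978	1213156	ACOT7	DISEASES
1	5183282	5310975	PANK1	DISEASES
1	109746686	109798391	SARS	DISEASES
1	159662035	159702036	CRP	DISEASES
1	237043747	237083748	MTR	DISEASES
2	1216910	1226490	HES2	DISEASES
2	3476454	3530527	TFRC	DISEASES
2	5273221	5373073	PNLIP	DISEASES
2	7162117	7304876	AMN	DISEASES
2	170041859	170165661	LRP2	DISEASES
3	1220081	1269742	UBIAD1	DISEASES
3	5345262	5491154	IFITM2	DISEASES
3	7399221	7510119	TGM5	DISEASES
3	133444793	133495614	TF	DISEASES
3	158368160	158408161	LXN	DISEASES
4	1014906	1073082	MTHFR	DISEASES
4	3059203	3179679	HTN3	DISEASES
4	5473361	5555634	HBE1	DISEASES
4	7320223	7347025	DUT	DISEASES
4	70775698	70815920	CSN1S1	DISEASES
4	99930416	99970417	METAP1	DISEASES
5	1319867	1420570	MMACHC	review
5	3440874	3561514	ALB	DISEASES
5	5184048	5301456	GIF	DISEASES
5	178748429	178788430	ADAMTS2	DISEASES
6	1391844	1450901	SCP2	DISEASES
6	7419843	7519274	HP	DISEASES
6	70388870	70428871	LMBRD1	DISEASES
7	1159664	1242781	CTH	DISEASES
7	3453681	3599007	GYPA	DISEASES
7	5287358	5385401	MS4A3	DISEASES
7	7069947	7188198	HPR	DISEASES
8	1372162	1437755	F3	DISEASES
8	3460820	3544029	MMAA	review
8	5105753	5214458	PGA3	DISEASES
9	3399582	3535061	MTRR	review
9	5270302	5339496	PGA4	DISEASES
9	7285889	7416409	TNFAIP1	DISEASES
9	130549811	130589812	FPGS	DISEASES
9	131098553	131138554	SLC27A4	DISEASES
10	3223600	3317872	PRELID2	DISEASES
10	5395586	5401009	FADS1	DISEASES
10	7472911	7589392	GAST	DISEASES
10	17026008	17191907	CUBN	review
11	1058705	1181056	LIN9	DISEASES
11	3437863	3565975	HRH2	DISEASES
11	5112982	5135563	FTH1	DISEASES
11	7241136	7262822	ACLY	DISEASES
11	59610344	59650345	TCN1	review
12	5391844	5412323	CBL	DISEASES
12	6878083	6918084	CD4	DISEASES
12	7098687	7139099	MMD	DISEASES
12	110005616	110045617	MVK	DISEASES
13	1321118	1457797	THUMPD2	DISEASES
13	3424149	3533923	PGC	DISEASES
13	7448608	7586028	TYMS	DISEASES
13	25252832	25292833	ATP12A	DISEASES
13	100442811	100482812	CLYBL	DISEASES
14	1151585	1158775	TXNDC9	DISEASES
14	3426829	3436779	GNMT	DISEASES
14	5062445	5175186	CS	DISEASES
14	74732604	74772605	ABCD4	review
15	1040781	1143787	MMADHC	review
15	3443827	3465162	MUT	review
15	5145418	5183396	SHMT2	DISEASES
16	5020283	5132254	METAP2	DISEASES
16	7165052	7241708	CD320	review
16	23586958	23626959	NDUFAB1	DISEASES
17	1248496	1327667	HAT1	DISEASES
17	3464662	3519757	PON1	DISEASES
17	5202022	5236381	MMAB	review
17	7301502	7440790	SLC27A1	DISEASES
17	17440539	17480540	PEMT	DISEASES
18	1320973	1456179	METAP1D	DISEASES
18	3018561	3135062	GGH	DISEASES
18	7344023	7353711	ATP4A	DISEASES
18	74706711	74788653	MBP	DISEASES
19	1394635	1419406	CASR	DISEASES
19	5074873	5215437	SDS	DISEASES
19	5821155	5861156	FUT6	review
19	7403764	7495226	CD79A	DISEASES
20	1482810	1560665	ALDH1L1	DISEASES
20	7174475	7277312	FUT2	review
20	61316358	61411514	NTSR1	DISEASES
21	7411429	7421160	FTL	DISEASES
21	44453449	44503279	CBS	review
22	1237005	1262641	CP	DISEASES
22	3061672	3171788	TRDMT1	DISEASES
22	5396761	5441351	ATP4B	DISEASES
22	31003365	31043366	TCN2	review
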