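gene	r_afr	p_perm_afr	r_amr	p_perm_amr	r_eur	p_perm_eur
ACOT7	-0.08	0.29	-0.11	0.17	0.13	0.0828
HES2	-0.08	0.29	-0.11	0.16	0.13	0.0823
UBIAD1	-0.09	0.27	-0.11	0.16	0.13	0.0871
MTHFR	-0.09	0.25	-0.11	0.16	0.13	0.0894
MMACHC	-0.10	0.22	-0.08	0.32	0.14	0.0729
SCP2	-0.11	0.16	-0.05	0.51	0.10	0.188
CTH	0.02	0.85	-0.05	0.5	0.05	0.542
F3	-0.05	0.52	-0.09	0.24	0.06	0.434
SARS	-0.08	0.3	-0.05	0.5	0.17	0.0274
CRP	-0.15	0.048	-0.01	0.86	0.07	0.377
LIN9	-0.10	0.22	-0.05	0.49	0.06	0.478
MTR	-0.01	0.85	-0.11	0.16	0.09	0.264
THUMPD2	-0.12	0.13	-0.01	0.93	0.12	0.12
TXNDC9	-0.05	0.48	-0.07	0.39	0.09	0.251
MMADHC	0.00	0.98	-0.15	0.054	0.14	0.0803
LRP2	-0.13	0.087	-0.05	0.52	0.09	0.259
HAT1	-0.16	0.033	-0.06	0.45	0.13	0.0863
METAP1D	-0.17	0.032	-0.06	0.46	0.13	0.087
CASR	-0.11	0.14	-0.08	0.29	0.14	0.0672
ALDH1L1	-0.06	0.47	-0.11	0.16	0.10	0.214
TF	0.00	0.98	-0.18	0.019	0.06	0.467
CP	-0.05	0.5	-0.17	0.026	0.16	0.0404
LXN	-0.02	0.77	-0.18	0.019	0.14	0.077
TFRC	-0.16	0.041	-0.04	0.6	0.16	0.0383
CSN1S1	0.03	0.69	-0.04	0.63	0.05	0.481
HTN3	0.03	0.69	-0.04	0.63	0.05	0.495
ALB	0.04	0.63	-0.06	0.41	0.03	0.678
METAP1	-0.07	0.36	0.06	0.4	0.07	0.38
GYPA	-0.10	0.21	0.01	0.86	0.16	0.0334
MMAA	-0.04	0.56	0.02	0.79	0.15	0.0592
MTRR	-0.04	0.64	-0.13	0.1	0.10	0.22
PRELID2	-0.05	0.53	-0.06	0.41	0.10	0.203
HRH2	-0.04	0.58	-0.10	0.2	0.10	0.191
ADAMTS2	-0.03	0.66	-0.16	0.042	0.09	0.223
PGC	-0.10	0.19	-0.09	0.25	0.14	0.0651
GNMT	-0.12	0.12	-0.08	0.28	0.13	0.0848
MUT	-0.15	0.057	-0.08	0.3	0.15	0.0451
LMBRD1	-0.11	0.17	-0.08	0.29	0.15	0.0499
PON1	-0.04	0.62	-0.08	0.29	0.05	0.489
GGH	0.00	0.96	-0.11	0.16	0.09	0.244
FPGS	-0.12	0.11	-0.19	0.012	0.14	0.0641
SLC27A4	-0.13	0.091	-0.20	0.0097	0.15	0.0602
CUBN	-0.08	0.31	-0.15	0.051	0.16	0.0375
TRDMT1	-0.08	0.31	-0.15	0.049	0.16	0.0437
PANK1	-0.13	0.092	-0.15	0.046	0.17	0.0264
PNLIP	-0.14	0.069	-0.16	0.042	0.17	0.0247
IFITM2	-0.08	0.32	-0.14	0.071	0.10	0.217
HBE1	-0.06	0.41	-0.11	0.16	0.08	0.303
GIF	-0.19	0.012	-0.20	0.011	0.24	0.00186
TCN1	-0.19	0.012	-0.20	0.011	0.24	0.00191
MS4A3	-0.19	0.013	-0.20	0.0099	0.24	0.00171
PGA3	-0.14	0.061	-0.21	0.0066	0.21	0.00607
PGA4	-0.14	0.064	-0.21	0.0066	0.21	0.00585
FADS1	-0.13	0.082	-0.21	0.006	0.21	0.00693
FTH1	-0.12	0.11	-0.21	0.0062	0.20	0.0097
CBL	-0.02	0.8	-0.25	0.0012	0.14	0.0759
CD4	-0.02	0.75	-0.04	0.62	0.12	0.113
CS	-0.10	0.2	0.03	0.72	0.09	0.245
SHMT2	-0.10	0.19	0.03	0.7	0.08	0.305
METAP2	-0.11	0.14	-0.02	0.79	0.14	0.0619
MMAB	-0.05	0.56	0.06	0.47	0.03	0.714
MVK	-0.05	0.56	0.06	0.47	0.03	0.714
SDS	-0.05	0.52	0.08	0.31	0.02	0.799
ATP12A	-0.04	0.62	-0.03	0.65	0.05	0.501
CLYBL	-0.13	0.087	-0.04	0.63	0.12	0.113
ATP4B	-0.08	0.32	-0.09	0.25	0.13	0.0822
ABCD4	0.00	1	-0.12	0.11	0.02	0.84
AMN	0.01	0.95	-0.05	0.51	-0.01	0.928
TGM5	-0.12	0.13	-0.06	0.43	0.16	0.0419
DUT	-0.13	0.084	-0.10	0.19	0.15	0.046
NDUFAB1	-0.10	0.19	0.00	0.95	0.10	0.202
HP	-0.08	0.32	0.00	0.99	0.06	0.435
HPR	-0.08	0.32	0.00	0.99	0.06	0.435
PEMT	0.02	0.81	-0.12	0.11	0.11	0.172
TNFAIP1	0.01	0.89	-0.13	0.082	0.10	0.195
GAST	0.08	0.31	-0.14	0.076	0.10	0.183
ACLY	0.08	0.3	-0.14	0.078	0.10	0.189
MMD	0.01	0.85	-0.12	0.12	0.12	0.13
TYMS	-0.12	0.14	-0.02	0.77	0.11	0.144
MBP	-0.03	0.66	-0.02	0.79	0.04	0.576
FUT6	-0.03	0.69	-0.15	0.048	0.11	0.14
CD320	-0.07	0.39	-0.10	0.21	0.07	0.346
SLC27A1	-0.10	0.21	-0.10	0.19	0.11	0.168
ATP4A	-0.03	0.66	-0.12	0.12	0.05	0.554
CD79A	0.00	0.97	-0.13	0.084	0.08	0.329
FUT2	-0.04	0.61	-0.14	0.068	0.15	0.0482
FTL	-0.05	0.51	-0.14	0.074	0.16	0.0336
NTSR1	0.06	0.44	-0.17	0.026	0.00	0.995
CBS	0.10	0.19	-0.12	0.13	0.01	0.879
TCN2	-0.02	0.75	-0.04	0.64	0.04	0.645
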