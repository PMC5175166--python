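# 52-TF catalogue with SYNTHETIC target members, for demos/tests only
RXRA	synthetic_toy	G0420	G0278	G0275	G0367	G0382	G0167	G0253	G0455	G0372	G0542	G0246	G0383	G0213	G0557	G0209
SRF	synthetic_toy	G0086	G0303	G0358	G0446	G0185	G0156	G0099	G0427	G0435	G0302	G0116	G0586	G0468	G0353	G0058
SPI1	synthetic_toy	G0053	G0393	G0127	G0215	G0473	G0412	G0420	G0106	G0485	G0439	G0060	G0077	G0360	G0098	G0575
YY1	synthetic_toy	G0235	G0226	G0074	G0499	G0442	G0067	G0580	G0448	G0520	G0423	G0105	G0051	G0590	G0298	G0537
PAX5	synthetic_toy	G0463	G0068	G0050	G0255	G0163	G0419	G0457	G0332	G0322	G0092	G0088	G0476	G0039	G0406	G0078
JUND	synthetic_toy	G0192	G0154	G0482	G0198	G0224	G0057	G0541	G0112	G0591	G0010	G0575	G0122	G0011	G0427	G0089
CTCF	synthetic_toy	G0130	G0034	G0440	G0233	G0439	G0513	G0086	G0363	G0416	G0165	G0297	G0314	G0512	G0554	G0231
CTCFL	synthetic_toy	G0348	G0524	G0433	G0116	G0434	G0259	G0143	G0304	G0056	G0279	G0453	G0094	G0341	G0399	G0454
E2F4	synthetic_toy	G0114	G0560	G0054	G0214	G0029	G0537	G0160	G0336	G0304	G0146	G0123	G0400	G0524	G0349	G0538
E2F6	synthetic_toy	G0074	G0355	G0026	G0184	G0132	G0440	G0087	G0027	G0205	G0538	G0235	G0277	G0226	G0058	G0349
MEF2A	synthetic_toy	G0459	G0299	G0208	G0295	G0089	G0329	G0433	G0347	G0088	G0590	G0216	G0530	G0270	G0519	G0580
ELF1	synthetic_toy	G0538	G0173	G0419	G0333	G0276	G0306	G0380	G0412	G0039	G0599	G0195	G0027	G0436	G0193	G0548
EGR1	synthetic_toy	G0592	G0135	G0033	G0419	G0522	G0183	G0519	G0231	G0270	G0580	G0159	G0249	G0526	G0123	G0277
SP1	synthetic_toy	G0203	G0292	G0309	G0358	G0222	G0169	G0152	G0529	G0462	G0330	G0242	G0417	G0422	G0583	G0114
POU2F2	synthetic_toy	G0588	G0045	G0492	G0528	G0375	G0569	G0134	G0422	G0591	G0014	G0083	G0504	G0252	G0481	G0548
ZNF263	synthetic_toy	G0034	G0304	G0105	G0402	G0371	G0306	G0173	G0558	G0310	G0165	G0449	G0426	G0230	G0182	G0066
USF1	synthetic_toy	G0324	G0499	G0403	G0509	G0571	G0269	G0520	G0163	G0051	G0471	G0470	G0294	G0066	G0497	G0550
SP2	synthetic_toy	G0285	G0185	G0461	G0537	G0444	G0088	G0535	G0428	G0445	G0267	G0477	G0590	G0290	G0127	G0131
ETS1	synthetic_toy	G0166	G0419	G0046	G0473	G0383	G0217	G0265	G0362	G0544	G0161	G0344	G0336	G0599	G0018	G0314
EBF1	synthetic_toy	G0375	G0520	G0169	G0185	G0096	G0256	G0191	G0451	G0104	G0100	G0423	G0447	G0465	G0350	G0340
THAP1	synthetic_toy	G0356	G0341	G0140	G0035	G0541	G0054	G0249	G0232	G0562	G0457	G0533	G0398	G0532	G0551	G0275
MYC	synthetic_toy	G0222	G0171	G0305	G0474	G0498	G0430	G0163	G0516	G0029	G0060	G0061	G0280	G0022	G0345	G0515
MYC::MAX	synthetic_toy	G0274	G0140	G0369	G0472	G0492	G0494	G0220	G0339	G0502	G0288	G0555	G0078	G0212	G0372	G0508
HNF4A	synthetic_toy	G0005	G0165	G0454	G0190	G0193	G0402	G0477	G0103	G0387	G0164	G0222	G0201	G0101	G0108	G0410
NR1H3::RXRA	synthetic_toy	G0232	G0033	G0307	G0229	G0093	G0567	G0025	G0311	G0207	G0446	G0416	G0019	G0384	G0290	G0542
MAX	synthetic_toy	G0515	G0510	G0529	G0536	G0266	G0426	G0424	G0565	G0004	G0589	G0500	G0506	G0290	G0388	G0331
NRF1	synthetic_toy	G0446	G0156	G0553	G0592	G0345	G0103	G0386	G0591	G0307	G0174	G0322	G0079	G0190	G0414	G0003
RXRA::VDR	synthetic_toy	G0196	G0298	G0112	G0001	G0108	G0597	G0526	G0284	G0247	G0012	G0567	G0563	G0535	G0332	G0008
JUN	synthetic_toy	G0211	G0316	G0091	G0266	G0254	G0192	G0263	G0338	G0131	G0187	G0282	G0013	G0157	G0417	G0535
REST	synthetic_toy	G0016	G0538	G0007	G0212	G0493	G0463	G0249	G0145	G0524	G0593	G0562	G0592	G0540	G0002	G0407
FOSL2	synthetic_toy	G0402	G0422	G0198	G0319	G0196	G0371	G0049	G0116	G0383	G0002	G0563	G0449	G0542	G0173	G0354
JUN::FOS	synthetic_toy	G0197	G0078	G0332	G0076	G0072	G0064	G0213	G0278	G0459	G0095	G0437	G0319	G0401	G0596	G0530
ZEB1	synthetic_toy	G0572	G0565	G0392	G0317	G0139	G0550	G0272	G0258	G0502	G0383	G0296	G0055	G0309	G0597	G0364
ZBTB33	synthetic_toy	G0504	G0507	G0590	G0244	G0481	G0499	G0148	G0448	G0319	G0356	G0527	G0231	G0537	G0457	G0273
GATA2	synthetic_toy	G0133	G0202	G0375	G0260	G0310	G0128	G0383	G0162	G0523	G0537	G0472	G0169	G0504	G0171	G0288
GATA1	synthetic_toy	G0349	G0535	G0547	G0435	G0101	G0337	G0085	G0022	G0592	G0487	G0341	G0537	G0112	G0364	G0006
BHLHE40	synthetic_toy	G0235	G0042	G0182	G0497	G0568	G0438	G0328	G0435	G0457	G0533	G0214	G0541	G0582	G0040	G0168
FOXA1	synthetic_toy	G0216	G0499	G0052	G0013	G0595	G0164	G0384	G0434	G0130	G0074	G0581	G0106	G0235	G0030	G0358
JUNB	synthetic_toy	G0304	G0120	G0030	G0495	G0086	G0263	G0073	G0200	G0287	G0252	G0002	G0589	G0303	G0128	G0476
FOS	synthetic_toy	G0045	G0198	G0037	G0214	G0525	G0397	G0196	G0552	G0378	G0070	G0134	G0514	G0143	G0185	G0256
FOSL1	synthetic_toy	G0492	G0420	G0594	G0165	G0098	G0439	G0424	G0112	G0102	G0477	G0259	G0221	G0286	G0056	G0397
NR2C2	synthetic_toy	G0379	G0087	G0465	G0234	G0534	G0335	G0262	G0520	G0153	G0271	G0334	G0459	G0439	G0577	G0115
TCF12	synthetic_toy	G0469	G0093	G0089	G0482	G0503	G0198	G0329	G0501	G0349	G0102	G0566	G0203	G0446	G0353	G0461
MEF2C	synthetic_toy	G0446	G0104	G0355	G0278	G0500	G0343	G0475	G0146	G0400	G0174	G0164	G0561	G0193	G0495	G0305
HNF4G	synthetic_toy	G0562	G0034	G0554	G0405	G0516	G0025	G0315	G0167	G0403	G0251	G0065	G0290	G0322	G0264	G0549
PPARG::RXRA	synthetic_toy	G0503	G0356	G0229	G0428	G0539	G0418	G0514	G0395	G0531	G0097	G0246	G0537	G0273	G0122	G0501
RXR::RAR_DR5	synthetic_toy	G0212	G0054	G0108	G0292	G0145	G0346	G0574	G0306	G0006	G0244	G0003	G0221	G0211	G0270	G0149
TAL1::GATA1	synthetic_toy	G0547	G0430	G0056	G0299	G0140	G0389	G0077	G0106	G0499	G0182	G0394	G0456	G0325	G0195	G0273
PBX3	synthetic_toy	G0070	G0281	G0316	G0548	G0557	G0446	G0184	G0576	G0342	G0452	G0069	G0428	G0553	G0331	G0369
ECR::USP	synthetic_toy	G0329	G0196	G0295	G0495	G0079	G0457	G0337	G0041	G0128	G0053	G0435	G0508	G0498	G0385	G0057
IRF4	synthetic_toy	G0029	G0593	G0320	G0139	G0081	G0480	G0493	G0377	G0567	G0347	G0522	G0216	G0409	G0105	G0358
FOXA2	synthetic_toy	G0597	G0148	G0036	G0449	G0554	G0271	G0119	G0265	G0342	G0456	G0548	G0372	G0117	G0127	G0200
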