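otu_id	mean	median	hpd_low	hpd_high	effect	taxonomy	note
New.ReferenceOTU369	-1.929	-1.904	-3.224	-0.699	-0.366	Genus Desulfovibrio
New.ReferenceOTU1337	1.859	1.871	0.158	3.403	0.353	Family Ruminococcaceae
New.ReferenceOTU381	1.838	1.858	0.110	3.435	0.349	Family Lachnospiraceae
New.ReferenceOTU1863	1.833	1.837	0.857	2.829	0.348	Order Clostridiales
207340	1.793	1.791	0.573	3.018	0.340	Family Mogibacteriaceae
New.ReferenceOTU570	-1.704	-1.624	-3.194	-0.475	-0.323	Genus Phascolarctobacterium
New.ReferenceOTU3941	1.611	1.598	0.745	2.548	0.306	Family Christensenellaceae
New.ReferenceOTU2872	1.546	1.536	0.659	2.449	0.293	Order Clostridiales
213671	-1.486	-1.488	-2.559	-0.290	-0.282	Family Rikenellaceae
New.ReferenceOTU3611	-1.481	-1.476	-2.675	-0.233	-0.281	Family Erysipelotrichaceae
New.ReferenceOTU3526	1.447	1.443	0.624	2.253	0.275	Family Lachnospiraceae
522353	-1.438	-1.439	-2.494	-0.406	-0.273	Genus Coprobacillus
New.ReferenceOTU4568	-1.428	-1.408	-2.572	-0.352	-0.271	Family Lachnospiraceae
644244	-1.423	-1.421	-2.532	-0.394	-0.270	Order Clostridiales
New.ReferenceOTU1522	1.400	1.404	0.168	2.561	0.266	Family Ruminococcaceae
New.ReferenceOTU3977	1.352	1.305	0.498	2.223	0.257	Family Lachnospiraceae
New.ReferenceOTU413	1.340	1.327	0.275	2.315	0.254	Family Ruminococcaceae
348609	1.317	1.309	0.493	2.123	0.250	Family Christensenellaceae
211066	-1.314	-1.310	-2.396	-0.189	-0.249	Family Ruminococcaceae
860192	-1.301	-1.297	-2.370	-0.293	-0.247	Genus Coprobacillus	sign of printed effect (0.247) corrected to match the negative posterior mean
New.ReferenceOTU4280	1.269	1.247	0.044	2.469	0.241	Species Gnavus
New.ReferenceOTU3816	1.216	1.217	0.051	2.323	0.231	Family Ruminococcaceae
New.ReferenceOTU3320	1.203	1.209	0.376	1.950	0.228	Order Clostridiales
New.ReferenceOTU2572	-1.194	-1.201	-2.156	-0.246	-0.227	Genus Coprobacillus
New.ReferenceOTU3360	1.189	1.203	0.269	2.046	0.226	Order Clostridiales
New.ReferenceOTU3820	-1.186	-1.181	-2.297	-0.016	-0.225	Order Clostridiales
New.ReferenceOTU1988	1.173	1.173	0.254	2.059	0.223	Order Clostridiales
New.ReferenceOTU362	1.165	1.140	0.026	2.341	0.221	Family Ruminococcaceae
New.ReferenceOTU1139	1.161	1.165	0.123	2.222	0.220	Family Lachnospiraceae
New.ReferenceOTU4624	-1.145	-1.147	-1.969	-0.325	-0.217	Family Ruminococcaceae
New.ReferenceOTU669	-1.125	-1.135	-2.059	-0.125	-0.213	Family Ruminococcaceae
266198	1.108	1.113	0.031	2.120	0.210	Order RF39
New.ReferenceOTU591	1.102	1.107	0.174	1.971	0.209	Family Peptococcaceae
1108356	1.097	1.096	0.195	2.048	0.208	Order RF39
New.ReferenceOTU2960	-1.093	-1.094	-1.780	-0.433	-0.207	Order Clostridiales	printed median -1.0.94 read as -1.094
New.ReferenceOTU4631	1.093	1.106	0.123	2.094	0.207	Order Clostridiales
New.ReferenceOTU1502	1.066	1.068	0.322	1.717	0.202	Genus Blautia	printed median 0.068 read as 1.068 (lies inside the HPD interval)
New.ReferenceOTU1728	1.055	1.067	0.098	2.060	0.200	Genus Coprococcus
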