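otu_id	mean	median	hpd_low	hpd_high	effect	taxonomy	note
New.ReferenceOTU4438	-1.907	-1.890	-3.488	-0.393	-0.322	Family S24-7
209947	-1.867	-1.844	-3.478	-0.352	-0.315	Order Clostridiales
New.ReferenceOTU4568	-1.537	-1.546	-2.862	-0.328	-0.260	Family Lachnospiraceae
339336	-1.440	-1.439	-2.456	-0.341	-0.244	Order Clostridiales
New.ReferenceOTU3820	-1.438	-1.435	-2.344	-0.577	-0.243	Order Clostridiales
860192	-1.389	-1.389	-2.355	-0.452	-0.235	Genus Coprobacillus
522353	-1.355	-1.351	-2.312	-0.375	-0.229	Genus Coprobacillus
New.ReferenceOTU2572	-1.327	-1.322	-2.300	-0.455	-0.224	Genus Coprobacillus
New.ReferenceOTU1080	-1.310	-1.312	-2.093	-0.548	-0.221	Genus Blaultia
641783	1.276	1.276	0.367	2.219	0.215	Family Ruminococcae
New.ReferenceOTU782	1.271	1.268	0.256	2.315	0.215	Unassigned
New.ReferenceOTU776	1.252	1.249	0.148	2.276	0.212	Family Lachnospiraceae
554303	-1.245	-1.244	-2.055	-0.476	-0.211	Family Lachnospiraceae
New.ReferenceOTU2945	1.210	1.203	0.452	2.030	0.205	Unassigned
New.ReferenceOTU3271	1.194	1.195	0.055	2.461	0.202	Order Clostridiales
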