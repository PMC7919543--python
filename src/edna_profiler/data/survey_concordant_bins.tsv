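taxon	total_reads	summed_composition	average_composition	n_positive	edna_rank	cpue	cpue_rank
Moxostoma_anisurum	809373	106.367	2.474	43	1	2.555	9
Semotilus_atromaculatus	292352	95.445	2.220	43	2	4.134	7
CYPRINID2	286456	79.818	1.995	40	3	66.947	1
Micropterus_dolomieu	211714	73.247	1.878	39	4	9.751	2
Ambloplites_rupestris	186779	69.235	1.871	37	5	6.225	4
Ictalurus_punctatus	182979	59.982	1.935	31	6	0.964	21
Etheostoma_flabellare	127742	54.875	1.892	29	7	0.153	36
Percina_caprodes	94546	48.174	1.784	27	8	1.977	11
Cyprinella_spiloptera	101071	40.770	1.853	22	9	6.906	3
Sander_vitreus	104568	32.707	1.817	18	10	1.254	17
Lepomis_gibbosus	67622	30.705	1.335	23	11	1.938	13
Etheostoma_nigrum	36510	29.237	1.271	23	12	0.835	22
CYPRINID3	13704	27.870	0.845	33	13	0.820	24
Rhinichthys_cataractae	40552	23.362	1.947	12	14	0.565	26
Ameiurus_nebulosus	15700	16.997	1.416	12	15	0.625	25
Catostomus_commersonii	22848	15.034	1.670	9	16	1.454	16
Esox_lucius	15440	14.722	1.338	11	17	0.140	38
Culaea_inconstans	19210	14.372	1.796	8	18	0.517	27
ACIPENSER	19681	13.435	1.493	9	19	1.710	14
CYPRINID1	9923	12.651	2.108	6	20	1.152	18
Etheostoma_olmstedi	24478	11.911	1.702	7	21	1.965	12
Notemigonus_crysoleucas	7242	9.109	1.822	5	22	0.981	20
Micropterus_salmoides	14773	8.776	1.755	5	23	0.129	39
Exoglossum_maxillingua	4698	7.805	1.951	4	24	0.194	35
Cyprinus_carpio	23540	7.494	1.874	4	25	0.071	42
Perca_flavescens	14713	7.031	1.758	4	26	3.636	8
Esox_masquinongy	8038	6.337	1.267	5	27	0.277	30
ICHTHYOMYZON	2082	3.673	1.224	3	28	NA	NA
Pimephales_promelas	72	3.118	1.559	2	29	0.265	32
Pomoxis_nigromaculatus	1996	1.605	1.605	1	30	0.061	43
Noturus_gyrinus	1840	1.519	1.519	1	31	NA	NA
Ammocrypta_pellucida	454	1.282	1.282	1	32	0.246	33
Umbra_limi	574	1.161	1.161	1	33	0.142	37
Etheostoma_exile	1	NA	0.000	0	NA	0.018	46
LETHENTERON-PETROMYZON	9	NA	0.000	0	NA	0.001	50
Morone_americana	1	NA	0.000	0	NA	0.006	47
Notropis_stramineus	4	NA	0.000	0	NA	2.299	10
Noturus_flavus	1	NA	0.000	0	NA	NA	NA
Percina_copelandi	83	NA	0.000	0	NA	0.128	40
Salmo_trutta	20	NA	0.000	0	NA	0.006	48
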