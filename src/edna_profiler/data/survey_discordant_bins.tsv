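taxon	total_reads	observed	cpue	cpue_rank	category
Rhinichthys_atratulus	1104	1	1.665	15	contaminant-flagged
SALVELINUS	10972	1	0.832	23	contaminant-flagged
Cottus_cognatus	66	1	0.021	44	contaminant-flagged
Salmo_salar	745	1	0.019	45	contaminant-flagged
Anguilla_rostrata	NA	1	0.001	51	capture-only
Fundulus_diaphanus	NA	1	0.078	41	capture-only
Lepisosteus_osseus	NA	1	1.110	19	capture-only
Lepomis_macrochirus	NA	1	0.300	29	capture-only
Hybognathus_hankinsoni	NA	1	0.494	28	no-reference
Labidesthes_sicculus	NA	1	0.270	31	no-reference
Moxostoma_macrolepidotum	NA	1	0.234	34	no-reference
Moxostoma_valenciennesi	NA	1	0.006	49	no-reference
Notropis_rubellus	NA	1	4.875	6	no-reference
Semotilus_corporalis	NA	1	5.023	5	no-reference
Ameiurus_melas	735	0	NA	NA	edna-only-consistent
Catostomus_catostomus	227	0	NA	NA	edna-only-consistent
Lepomis_auritus	416	0	NA	NA	edna-only-consistent
Oncorhynchus_mykiss	31	0	NA	NA	edna-only-consistent
Campostoma_anomalum	3	0	NA	NA	edna-only-possible
Carassius_auratus	1	0	NA	NA	edna-only-possible
Clinostomus_elongatus	4	0	NA	NA	edna-only-possible
Noturus_insignis	1	0	NA	NA	edna-only-possible
Oncorhynchus_tshawytscha	1642	0	NA	NA	edna-only-possible
Sander_canadensis	24	0	NA	NA	edna-only-possible
Ameiurus_catus	341	0	NA	NA	edna-only-contradicts
Etheostoma_caeruleum	4	0	NA	NA	edna-only-contradicts
Exoglossum_laurae	6	0	NA	NA	edna-only-contradicts
Hybopsis_amblops	15	0	NA	NA	edna-only-contradicts
Nocomis_biguttatus	2	0	NA	NA	edna-only-contradicts
Percina_maculata	395	0	NA	NA	edna-only-contradicts
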