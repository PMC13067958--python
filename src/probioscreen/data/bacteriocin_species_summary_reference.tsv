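species	n_genomes	pct_with_any	total_abundance	unique_types	dominant	notes
L. plantarum	1233	95.1	5118	27	Plantaricin F; Plantaricin E; Plantaricin J	Strong producer
L. rhamnosus	331	100.0	1091	7	Enterocin X β; Carnocin CP52; LSEI 2386	Strong producer
L. salivarius	240	100.0	761	16	Enterolysin A; Enterolysin A; Salivaricin P	Strong producer
L. gasseri	223	100.0	725	13	Helveticin J; Pediocin; Enterolysin A	Strong producer
L. reuteri	310	89.0	535	8	Enterolysin A; Enterolysin A; Acidocin LF221B	Strong producer
L. crispatus	112	100.0	514	12	Enterolysin A; Helveticin J; Helveticin J	Strong producer
L. paragasseri	71	100.0	350	14	Helveticin J; Pediocin; LS2 bacteriocin	Moderate
L. acidophilus	93	100.0	278	3	Helveticin J; Enterolysin A; Enterocin X β	Moderate
L. helveticus	93	100.0	277	4	Helveticin J; Enterolysin A; Helveticin J	Moderate
L. pentosus	111	97.3	218	10	Pediocin; Plantaricin NC8 α; Plantaricin NC8 β	Moderate
L. taiwanensis	29	100.0	194	11	Pediocin; Helveticin J; Lactacin F lafA	Moderate
L. brevis	120	87.5	153	7	Enterolysin A; Enterolysin A; Helveticin J	Moderate
L. johnsonii	35	100.0	129	13	Helveticin J; Pediocin; Lactacin F lafA	Moderate
L. paraplantarum	24	100.0	118	13	Plantaricin F; Plantaricin E; Plantaricin A	Moderate
L. delbrueckii	60	100.0	104	5	Enterolysin A; Helveticin J; Bovicin 255	Moderate
L. murinus	18	100.0	85	12	Enterolysin A; Closticin 574; Sakacin G	Moderate
L. paracasei	17	100.0	54	7	Enterocin X β; Carnocin CP52; LSEI 2386	Moderate
L. curvatus	67	32.8	50	14	Putative bacteriocin; Sakacin Q; Sakacin P	Low/none
L. argentoratensis	33	90.9	50	10	Enterocin X β; Plantaricin E; Plantaricin K	Low/none
L. jensenii	63	55.6	47	2	Enterolysin A; Enterolysin A	Low/none
L. intestinalis	10	100.0	39	6	Helveticin J; Enterolysin A; Plantaricin S β	Low/none
L. parabuchneri	27	100.0	30	3	Helveticin J; Enterolysin A; Enterolysin A	Low/none
L. fermentum	74	33.8	29	4	Enterolysin A; Enterolysin A; Acidocin B	Low/none
L. agilis	37	54.1	26	4	Plantaricin 423; MR10B; Bovicin 255	Low/none
L. sakei	15	73.3	22	9	Putative bacteriocin; Carnocin CP52; Plantaricin S α	Low/none
L. iners	73	24.7	21	3	Mutacin II; Enterolysin A; Putative bacteriocin	Low/none
A. kunkeei	106	17.9	20	3	Nisin A; Plantaricin S β; Plantaricin E	Low/none
L. vaginalis	20	90.0	20	2	Enterolysin A; Enterolysin A	Low/none
L. hilgardii	10	70.0	16	6	Helveticin J; Zoocin A; Plantaricin NC8 α	Low/none
L. mucosae	16	75.0	15	2	Enterolysin A; Enterolysin A	Low/none
C. paralimentarius	12	91.7	12	2	Carnocin CP52; Putative bacteriocin	Low/none
L. mulieris	43	20.9	11	3	Enterolysin A; Enterocin NKR-5-3A; Brochocin C	Low/none
F. sanfranciscensis	51	13.7	10	3	Pediocin; Lacticin 3147 A2; Lacticin 3147 A1	Low/none
L. aviarius	23	0.0	0	0	None	Low/none
F. fructivorans	13	0.0	0	0	None	Low/none
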