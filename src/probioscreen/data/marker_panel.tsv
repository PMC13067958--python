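marker_id	pattern	fields	category	subcategory
bsh	\b(bsh|choloylglycine hydrolase|bile salt hydrolase)\b	gene|product	Acid tolerance and energy metabolism	Bile salt resistance
gadA	\b(gadA|glutamate decarboxylase alpha)\b	gene|product	Amino acid and general metabolism	GABA production
gadB	\b(gadB|glutamate decarboxylase beta)\b	gene|product	Amino acid and general metabolism	GABA production
gadC	\b(gadC|glutamate/gamma-aminobutyrate antiporter)\b	gene|product	Amino acid and general metabolism	GABA production
srtA	\b(srtA|sortase)\b	gene|product	Cell envelope and EPS biosynthesis	Surface adhesion proteins
spa_pili	\b(spa[ABC]|pilin|fimbrial protein|LPXTG)\b	gene|product|note	Cell envelope and EPS biosynthesis	Biofilm adhesion proteins
eps	\b(eps[A-Z]|exopolysaccharide biosynthesis protein)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
wzx_wzy	\b(wzx|wzy)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
wzb_wzc	\b(wzb|wzc)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
gtf	\b(gtf[A-Z]?|glucosyltransferase)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
rfb	\brfb[A-Z]\b	gene	Cell envelope and EPS biosynthesis	EPS biosynthesis
ugd	\b(ugd|UDP-glucose 6-dehydrogenase)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
gnd	\b(gnd|6-phosphogluconate dehydrogenase)\b	gene|product	Cell envelope and EPS biosynthesis	EPS biosynthesis
groEL	\b(groEL|chaperonin GroEL|60 kDa chaperonin)\b	gene|product	Cold and heat stress tolerance	Heat stress tolerance
dnaK	\b(dnaK|chaperone protein DnaK)\b	gene|product	Cold and heat stress tolerance	Heat stress tolerance
clpC	\b(clpC|Clp protease ATP-binding subunit ClpC)\b	gene|product	Cold and heat stress tolerance	Heat stress tolerance
clpP	\b(clpP|Clp protease proteolytic subunit)\b	gene|product	Cold and heat stress tolerance	Heat stress tolerance
csp	\b(csp[A-E]|cold[- ]shock protein)\b	gene|product	Cold and heat stress tolerance	Cold stress tolerance
sodA	\b(sodA|superoxide dismutase)\b	gene|product	Cold and heat stress tolerance	Oxidative stress tolerance
kat	\b(kat[AE]?|catalase)\b	gene|product	Cold and heat stress tolerance	Oxidative stress tolerance
ahpC	\b(ahpC|alkyl hydroperoxide reductase)\b	gene|product	Cold and heat stress tolerance	Oxidative stress tolerance
fol	\b(fol[A-P]|dihydrofolate reductase|dihydropteroate synthase)\b	gene|product	Vitamin and cofactor biosynthesis	Folate biosynthesis
rib	\b(rib[A-HT]|riboflavin biosynthesis protein|riboflavin synthase)\b	gene|product	Vitamin and cofactor biosynthesis	Riboflavin biosynthesis
thi	\b(thi[A-OS]|thiamine[- ]phosphate synthase|thiamine biosynthesis)\b	gene|product	Vitamin and cofactor biosynthesis	Thiamine biosynthesis
atpA	\b(atpA|ATP synthase subunit alpha)\b	gene|product	Acid tolerance and energy metabolism	F0F1 ATPase
atp_operon	\b(atp[B-H]|ATP synthase subunit (beta|gamma|delta|epsilon))\b	gene|product	Acid tolerance and energy metabolism	F0F1 ATPase
arc	\b(arc[ABCDT]|arginine deiminase|ornithine carbamoyltransferase|carbamate kinase)\b	gene|product	Acid tolerance and energy metabolism	Arginine deiminase system
mub	\b(mub[A-Z]?|mucus[- ]binding protein)\b	gene|product	Cell envelope and EPS biosynthesis	Gut persistence factors
cna	\b(cna|collagen[- ]binding adhesin)\b	gene|product	Cell envelope and EPS biosynthesis	Surface adhesion proteins
fbpA	\b(fbpA|fibronectin[- ]binding protein)\b	gene|product	Cell envelope and EPS biosynthesis	Surface adhesion proteins
slp	\b(slp[AB]|S-layer protein)\b	gene|product	Cell envelope and EPS biosynthesis	Surface adhesion proteins
bacteriocin_general	\b(bacteriocin|lantibiotic|ribosomally synthesized and post-translationally modified)\b	gene|product|note	Bacteriocin and antimicrobial peptide production	Bacteriocin biosynthesis
pln	\b(pln[A-Z]|plantaricin)\b	gene|product	Bacteriocin and antimicrobial peptide production	Bacteriocin biosynthesis
pdu	\b(pdu[A-Z]|propanediol dehydratase|diol dehydratase)\b	gene|product	Bacteriocin and antimicrobial peptide production	Reuterin system
cob_cbi	\b(cob[A-Z]|cbi[A-Z]|cobalamin biosynthesis protein|adenosylcobinamide)\b	gene|product	Bacteriocin and antimicrobial peptide production	Reuterin system
pts	\b(pts[A-Z]?|PTS system|phosphotransferase system)\b	gene|product	Carbohydrate utilization and transport	PTS transport
lac	\b(lac[A-Z]|beta-galactosidase)\b	gene|product	Carbohydrate utilization and transport	Sugar transport and catabolism
gal	\b(gal[EKMT]|galactokinase)\b	gene|product	Carbohydrate utilization and transport	Sugar transport and catabolism
man	\b(man[A-Z]|mannose-6-phosphate isomerase)\b	gene|product	Carbohydrate utilization and transport	Sugar transport and catabolism
rbs	\b(rbs[A-DKR]|ribose import ATP-binding protein|ribose ABC transporter)\b	gene|product	Carbohydrate utilization and transport	Sugar transport and catabolism
cas	\b(cas[0-9]+[a-z]?|CRISPR-associated endonuclease|CRISPR-associated protein)\b	gene|product	Defense systems and CRISPR-Cas	CRISPR-Cas systems
dltA	\b(dltA|D-alanine--poly\(phosphoribitol\) ligase)\b	gene|product	Cell envelope and EPS biosynthesis	D-alanylation of teichoic acids
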