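# Biolog GEN III 71-carbon-source panel for the sulfur-oxidizer study strain.
# RECONSTRUCTED fixture: the study's per-well OmniLog values live in its
# unpublished supplement; this table reproduces the published marginals
# (16 in-vivo positive substrates; final-model concordance 11 TP, 52 TN,
# 3 FP, 5 FN over 71 wells) with synthetic OU values drawn in two bands
# around the 114-OU positivity threshold. Boundary wells are flagged and
# scored negative. model_call is the final-model simulated call.
substrate	metabolite_id	ou	call	model_call
Dextrin	unmapped	34	negative	negative
D-Maltose	unmapped	188	positive	positive
D-Trehalose	unmapped	164	positive	positive
D-Cellobiose	unmapped	143	positive	negative
Gentiobiose	unmapped	41	negative	negative
Sucrose	unmapped	207	positive	positive
D-Turanose	unmapped	58	negative	negative
Stachyose	unmapped	29	negative	negative
D-Raffinose	unmapped	63	negative	negative
alpha-D-Lactose	unmapped	47	negative	negative
D-Melibiose	unmapped	82	negative	negative
beta-Methyl-D-Glucoside	unmapped	55	negative	negative
D-Salicin	unmapped	38	negative	negative
N-Acetyl-D-Glucosamine	unmapped	72	negative	negative
N-Acetyl-beta-D-Mannosamine	unmapped	44	negative	negative
N-Acetyl-D-Galactosamine	unmapped	52	negative	negative
N-Acetyl-Neuraminic-Acid	unmapped	26	negative	negative
alpha-D-Glucose	glc__D_e	251	positive	positive
D-Mannose	man_e	197	positive	positive
D-Fructose	fru_e	232	positive	positive
D-Galactose	gal_e	171	positive	positive
3-Methyl-Glucose	unmapped	49	negative	negative
D-Fucose	unmapped	66	negative	negative
L-Fucose	unmapped	57	negative	negative
L-Rhamnose	unmapped	39	negative	negative
Inosine	unmapped	61	negative	negative
D-Sorbitol	sbt__D_e	159	positive	positive
D-Mannitol	mnl_e	152	positive	negative
D-Arabitol	unmapped	43	negative	negative
myo-Inositol	unmapped	36	negative	negative
Glycerol	glyc_e	243	positive	positive
D-Glucose-6-PO4	g6p_e	88	negative	positive
D-Fructose-6-PO4	f6p_e	93	negative	positive
D-Aspartic-Acid	unmapped	51	negative	negative
D-Serine	unmapped	33	negative	negative
Gelatin	unmapped	27	negative	negative
Glycyl-L-Proline	unmapped	45	negative	negative
L-Alanine	unmapped	69	negative	negative
L-Arginine	unmapped	54	negative	negative
L-Aspartic-Acid	unmapped	76	negative	negative
L-Glutamic-Acid	unmapped	84	negative	negative
L-Histidine	unmapped	31	negative	negative
L-Pyroglutamic-Acid	unmapped	48	negative	negative
L-Serine	unmapped	91	negative	negative
Pectin	unmapped	24	negative	negative
D-Galacturonic-Acid	unmapped	56	negative	negative
L-Galactonic-Acid-Lactone	unmapped	42	negative	negative
D-Gluconic-Acid	glcn_e	176	positive	negative
D-Glucuronic-Acid	unmapped	62	negative	negative
Glucuronamide	unmapped	37	negative	negative
Mucic-Acid	unmapped	46	negative	negative
Quinic-Acid	unmapped	53	negative	negative
D-Saccharic-Acid	unmapped	40	negative	negative
p-Hydroxy-Phenylacetic-Acid	unmapped	28	negative	negative
Methyl-Pyruvate	pyr_e	134	positive	negative
D-Lactic-Acid-Methyl-Ester	unmapped	65	negative	negative
L-Lactic-Acid	lac__L_e	97	negative	positive
Citric-Acid	cit_e	127	positive	negative
alpha-Keto-Glutaric-Acid	unmapped	78	negative	negative
D-Malic-Acid	unmapped	59	negative	negative
L-Malic-Acid	mal__L_e	183	positive	positive
Bromo-Succinic-Acid	unmapped	35	negative	negative
Tween-40	unmapped	110	boundary	negative
gamma-Amino-Butyric-Acid	unmapped	67	negative	negative
alpha-Hydroxy-Butyric-Acid	unmapped	113	boundary	negative
beta-Hydroxy-DL-Butyric-Acid	unmapped	50	negative	negative
alpha-Keto-Butyric-Acid	unmapped	32	negative	negative
Acetoacetic-Acid	unmapped	64	negative	negative
Propionic-Acid	unmapped	73	negative	negative
Acetic-Acid	ac_e	221	positive	positive
Formic-Acid	unmapped	30	negative	negative
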