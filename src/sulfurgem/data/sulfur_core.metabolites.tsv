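# Bundled sulfur-oxidation core network: metabolites.
# Formulas/charges at pH 7 conventions (BiGG-style); compartments: c cytoplasm,
# p periplasm, e extracellular.
id	name	formula	charge	compartment
s_e	Elemental sulfur (extracellular)	S	0	e
h2s_e	Hydrogen sulfide (extracellular)	H2S	0	e
s2o3_e	Thiosulfate (extracellular)	O3S2	-2	e
s4o6_e	Tetrathionate (extracellular)	O6S4	-2	e
so4_e	Sulfate (extracellular)	O4S	-2	e
o2_e	Oxygen (extracellular)	O2	0	e
co2_e	Carbon dioxide (extracellular)	CO2	0	e
h2o_e	Water (extracellular)	H2O	0	e
h_e	Proton (extracellular)	H	1	e
pi_e	Phosphate (extracellular)	HO4P	-2	e
h2s_p	Hydrogen sulfide (periplasm)	H2S	0	p
s_p	Elemental sulfur (periplasm)	S	0	p
s2o3_p	Thiosulfate (periplasm)	O3S2	-2	p
s4o6_p	Tetrathionate (periplasm)	O6S4	-2	p
so4_p	Sulfate (periplasm)	O4S	-2	p
h_p	Proton (periplasm)	H	1	p
h2o_p	Water (periplasm)	H2O	0	p
s_c	Elemental sulfur (cytoplasm)	S	0	c
so3_c	Sulfite	O3S	-2	c
s2o3_c	Thiosulfate (cytoplasm)	O3S2	-2	c
so4_c	Sulfate (cytoplasm)	O4S	-2	c
q8_c	Ubiquinone-8	C49H74O4	0	c
q8h2_c	Ubiquinol-8	C49H76O4	0	c
atp_c	ATP	C10H12N5O13P3	-4	c
adp_c	ADP	C10H12N5O10P2	-3	c
pi_c	Phosphate	HO4P	-2	c
h_c	Proton (cytoplasm)	H	1	c
h2o_c	Water (cytoplasm)	H2O	0	c
o2_c	Oxygen (cytoplasm)	O2	0	c
co2_c	Carbon dioxide (cytoplasm)	CO2	0	c
nad_c	NAD+	C21H26N7O14P2	-1	c
nadh_c	NADH	C21H27N7O14P2	-2	c
nadp_c	NADP+	C21H25N7O17P3	-3	c
nadph_c	NADPH	C21H26N7O17P3	-4	c
3pg_c	3-Phospho-D-glycerate	C3H4O7P	-3	c
13dpg_c	1,3-Bisphospho-D-glycerate	C3H4O10P2	-4	c
g3p_c	Glyceraldehyde 3-phosphate	C3H5O6P	-2	c
dhap_c	Dihydroxyacetone phosphate	C3H5O6P	-2	c
fdp_c	Fructose 1,6-bisphosphate	C6H10O12P2	-4	c
f6p_c	Fructose 6-phosphate	C6H11O9P	-2	c
e4p_c	Erythrose 4-phosphate	C4H7O7P	-2	c
x5p_c	Xylulose 5-phosphate	C5H9O8P	-2	c
r5p_c	Ribose 5-phosphate	C5H9O8P	-2	c
ru5p_c	Ribulose 5-phosphate	C5H9O8P	-2	c
rb15bp_c	Ribulose 1,5-bisphosphate	C5H8O11P2	-4	c
s7p_c	Sedoheptulose 7-phosphate	C7H13O10P	-2	c
s17bp_c	Sedoheptulose 1,7-bisphosphate	C7H12O13P2	-4	c
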