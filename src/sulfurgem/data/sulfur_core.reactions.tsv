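# Bundled sulfur-oxidation core network, version 1.
# A minimal compartmentalized model of aerobic chemolithotrophic growth on
# elemental sulfur: outer-membrane sulfur activation (OMP), the periplasmic and
# cytoplasmic sulfur-oxidation enzymes (SQR, SDO, TQO, TetH, Sox, TST/HDR,
# APS pathway + ATP sulfurylase), a proton-translocating respiratory chain with
# three terminal oxidases, reverse (uphill) NADH dehydrogenase, and the CBB
# carbon-fixation cycle in two variants: "incomplete" (SEBP-lacking, with the
# EC 2.2.1.2 transaldolase bypass) and "classical" (SBP aldolase + SBPase).
# Proton-translocation stoichiometries are textbook values: 6/4/2 H+ per quinol
# at the aa3/bo3/bd oxidases, 4 H+ per ATP at the synthase, 4 H+ pumped per
# NADH at complex I. Energy-substrate exchanges default to zero uptake.
# variant: empty = both builds; "incomplete" / "classical" = that build only.
id	equation	lb	ub	gene_rule	subsystem	variant
EX_s_e	s_e <=>	0	1000		Boundary
EX_h2s_e	h2s_e <=>	0	1000		Boundary
EX_s2o3_e	s2o3_e <=>	0	1000		Boundary
EX_s4o6_e	s4o6_e <=>	0	1000		Boundary
EX_so4_e	so4_e <=>	0	1000		Boundary
EX_o2_e	o2_e <=>	-1000	1000		Boundary
EX_co2_e	co2_e <=>	-1000	1000		Boundary
EX_h2o_e	h2o_e <=>	-1000	1000		Boundary
EX_h_e	h_e <=>	-1000	1000		Boundary
EX_pi_e	pi_e <=>	-1000	1000		Boundary
OMP	s_e + q8h2_c => h2s_p + q8_c	0	1000	omp	Sulfur oxidation
SQR	h2s_p + q8_c => s_p + q8h2_c	0	1000	sqr	Sulfur oxidation
SDO	s_c + o2_c + h2o_c => so3_c + 2 h_c	0	1000	sdo	Sulfur oxidation
CONDS	s_c + so3_c => s2o3_c	0	1000		Sulfur oxidation
HDR	s2o3_c + 3 h2o_c + 2 q8_c => 2 so3_c + 2 q8h2_c + 2 h_c	0	1000	tst and hdrA	Sulfur oxidation
SOX	s2o3_p + 5 h2o_p + 4 q8_c => 2 so4_p + 4 q8h2_c + 2 h_p	0	1000	soxA and soxB and soxX and soxY and soxZ	Sulfur oxidation
TQO	2 s2o3_p + q8_c + 2 h_p => s4o6_p + q8h2_c	0	1000	doxD	Sulfur oxidation
TETH	s4o6_p + h2o_p => s2o3_p + s_p + so4_p + 2 h_p	0	1000	tetH	Sulfur oxidation
APSSAT	so3_c + adp_c + pi_c + h_c + q8_c => so4_c + atp_c + q8h2_c	0	1000	aprAB and sat	Sulfur oxidation
CYTAA3	q8h2_c + 0.5 o2_c + 6 h_c => q8_c + h2o_c + 6 h_p	0	1000	ctaDCE	Respiration
CYTBO3	q8h2_c + 0.5 o2_c + 4 h_c => q8_c + h2o_c + 4 h_p	0	1000	cyoABCD	Respiration
CYTBD	q8h2_c + 0.5 o2_c + 2 h_c => q8_c + h2o_c + 2 h_p	0	1000	cydAB	Respiration
ATPS4R	adp_c + pi_c + 4 h_p <=> atp_c + h2o_c + 3 h_c	-1000	1000	atpABCDEFGH	Respiration
NADH16	nadh_c + q8_c + 5 h_c <=> nad_c + q8h2_c + 4 h_p	-1000	1000	nuoA	Respiration
THD	nadh_c + nadp_c <=> nad_c + nadph_c	-1000	1000	sthA	Respiration
ATPM	atp_c + h2o_c => adp_c + pi_c + h_c	0	1000		Maintenance
RBPC	rb15bp_c + co2_c + h2o_c => 2 3pg_c + 2 h_c	0	1000	cbbLS	CBB cycle
PGK	3pg_c + atp_c <=> 13dpg_c + adp_c	-1000	1000	pgk	CBB cycle
GAPD	13dpg_c + nadph_c + h_c => g3p_c + nadp_c + pi_c	0	1000	gap	CBB cycle
TPI	dhap_c <=> g3p_c	-1000	1000	tpiA	CBB cycle
FBA	dhap_c + g3p_c <=> fdp_c	-1000	1000	fba	CBB cycle
FBP	fdp_c + h2o_c => f6p_c + pi_c	0	1000	fbp	CBB cycle
TKT1	g3p_c + s7p_c <=> r5p_c + x5p_c	-1000	1000	tkt	CBB cycle
TKT2	f6p_c + g3p_c <=> e4p_c + x5p_c	-1000	1000	tkt	CBB cycle
RPI	r5p_c <=> ru5p_c	-1000	1000	rpiA	CBB cycle
RPE	ru5p_c <=> x5p_c	-1000	1000	rpe	CBB cycle
PRK	ru5p_c + atp_c => rb15bp_c + adp_c + h_c	0	1000	prk	CBB cycle
TALA	f6p_c + e4p_c <=> g3p_c + s7p_c	-1000	1000	talB	CBB cycle	incomplete
SBPA	dhap_c + e4p_c => s17bp_c	0	1000	fba	CBB cycle	classical
SBPASE	s17bp_c + h2o_c => s7p_c + pi_c	0	1000	sebp	CBB cycle	classical
BIOMASS	g3p_c + 20 atp_c + 20 h2o_c => 20 adp_c + 20 pi_c + 20 h_c	0	1000		Biomass
H2ST	h2s_e <=> h2s_p	-1000	1000		Transport
ST	s_p <=> s_c	-1000	1000		Transport
S2O3TE	s2o3_e <=> s2o3_p	-1000	1000		Transport
S2O3TC	s2o3_p <=> s2o3_c	-1000	1000		Transport
S4O6T	s4o6_e => s4o6_p	0	1000		Transport
SO4TC	so4_c => so4_p	0	1000		Transport
SO4TE	so4_p <=> so4_e	-1000	1000		Transport
O2T	o2_e <=> o2_c	-1000	1000		Transport
CO2T	co2_e <=> co2_c	-1000	1000		Transport
H2OT	h2o_e <=> h2o_c	-1000	1000		Transport
H2OTP	h2o_e <=> h2o_p	-1000	1000		Transport
HT	h_e <=> h_p	-1000	1000		Transport
HLEAK	h_p => h_c	0	1000		Transport
PIT	pi_e <=> pi_c	-1000	1000		Transport
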