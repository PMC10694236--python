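# Methods

## Scope and model

`sulfurgem` implements the constraint-based workflow used to build and
interrogate genome-scale metabolic models (GEMs) of chemolithotrophic
sulfur-oxidizing bacteria of the *Acidithiobacillus* type: merging two
annotation-derived draft reconstructions, repairing energy-generating cycles
(EGCs), installing a biomass objective with ATP maintenance, gap-filling
blocked biomass precursors against a universal reaction database, scoring the
model against a Biolog GEN III carbon-source panel, and enumerating
sulfur-oxidation pathways with their ATP/NAD(P)H/CO2/growth energetics.

All predictions are flux balance analysis (FBA): linear programs of the form
max/min c·v subject to S·v = 0 and lb ≤ v ≤ ub, where S is the
stoichiometric matrix (rows = metabolites, columns = reactions) and v is the
flux vector in mmol/gDW/h. Parsimonious FBA (pFBA) re-solves with the
objective pinned at its optimum and total absolute flux minimized (every
column split into forward/reverse non-negative parts), which selects the
shortest route among alternate optima; its support defines "the pathway"
wherever one is reported. Steady-state residuals are checked below 1e-6;
solver feasibility/optimality tolerances are 1e-9; fluxes under 1e-6 are
treated as zero in active sets. LPs are solved with HiGHS (via SciPy), which
is deterministic for a fixed model ordering. Because an optimal flux vector
can be degenerate while the optimum is unique, objective values are the
contract; `flux_range` certifies per-reaction uniqueness when needed.

## Curation stages

**Merging.** Union by identifier. Identical ids with different stoichiometry
abort with both equations printed; differing bounds merge to the union of
allowed directions (logged); gene rules merge by OR.

**Energy-generating cycles.** An EGC is a thermodynamically impossible loop
that produces an energy currency with every exchange closed. Detection: for
each currency (ATP, GTP, NADH, NADPH, FADH2, ubiquinol, and a
proton-motive-force probe moving a periplasmic proton inward), block uptake
on all exchanges, add a dissipation probe, maximize. Any optimum above 1e-6
flags the currency and the pFBA support of the probe optimum is reported as
the cycle. The audited currency set is wider than ATP alone because a cycle
in any of these pools can be laundered into ATP by the respiratory chain.
Repair walks the flagged cycles deterministically (currency order, then
sorted reaction ids) and applies the first direction restriction sanctioned
by a user-supplied directionality reference (e.g. MetaCyc-derived), then
re-detects, until every currency optimum is zero. A cycle with no
reference-covered member is an error, never silently forced.

**Biomass and precursors.** `install_biomass` builds a biomass reaction from
a precursor table plus a growth-associated maintenance (GAM) term hydrolyzing
ATP inside the biomass equation, and a separate always-on non-growth
maintenance (NGAM) reaction with both bounds at the stated rate. Precursor
producibility is probed per metabolite by maximizing a temporary demand under
the growth medium; optima under 1e-6 flag the precursor as blocked.

**Gap-filling.** Weight-added parsimonious gap-filling: a single LP over the
union of the model and the universal database minimizing Σ w_i·|v_i| over
database reactions (model reactions weigh zero) subject to steady state and
target flux ≥ 0.05 mmol/gDW/h (configurable; the support cutoff for "added"
reactions scales down with the threshold so near-threshold routes are never
dropped). This is the LP relaxation of minimal-set gap-filling: it can in
principle include flux-coupled extras a MILP would avoid, so reports label
the added set "parsimonious (LP)". Tests bracket its weighted cost between
an exhaustive minimal-set search (below) and the seeded ground-truth cost
(above) on synthetic instances.

## Phenotype concordance

Biolog GEN III wells are called positive iff the OmniLog signal exceeds
114 OU (strict inequality); ambiguous "boundary" wells are scored negative
but stay flagged. Growth simulation opens the substrate's exchange at
10 mmol/gDW/h on top of a base medium and calls positive iff the biomass
optimum exceeds 1e-6 h^-1. For a chemolithotroph the base medium keeps the
inorganic energy source open — a carbon source alone powers nothing — and
closes the native carbon/energy exchange when, as in the toy fixtures, the
two coincide. The confusion table reports TP/TN/FP/FN with
agreement = 100·(TP+TN)/N and N stated explicitly (published agreement
figures for such panels have been printed against both N and N+1
denominators; this package always reports its own N). Model extension
resolves experimentally-positive/model-negative wells either by importing
transport+exchange entries from the database (wells with no exchange) or by
gap-filling the biomass objective under that substrate (wells with no
utilization route); unfixable wells remain listed as residual false
negatives. Extension is monotone: it only adds reactions, so TP cannot drop
and FN cannot grow.

The bundled 71-well panel is a **reconstruction**: the study's per-well OU
values are in an unpublished supplement, so the fixture reproduces the
published marginals (16 in-vivo positives; 11 TP, 52 TN, 3 FP, 5 FN;
agreement 63/71 = 88.7%) with synthetic OU values drawn in two bands well
clear of the 114 threshold. It supports the concordance arithmetic exactly,
but not per-substrate claims.

## The bundled sulfur-oxidation core

`data/sulfur_core.reactions.tsv` defines a 47-metabolite, 53-reaction
compartmentalized (cytoplasm/periplasm/extracellular) model of aerobic
growth on elemental sulfur. Sulfur chemistry: outer-membrane activation of
S0 to sulfide (OMP, quinol-dependent), sulfide:quinone oxidoreductase (SQR),
cytoplasmic sulfur dioxygenase (SDO), non-enzymatic S + SO3^2- → S2O3^2-
condensation, a rhodanese/heterodisulfide-reductase lump (TST/HDR) oxidizing
thiosulfate's sulfane sulfur to sulfite with quinone reduction, the
periplasmic Sox system, thiosulfate:quinone oxidoreductase (TQO) and
tetrathionate hydrolase (TetH), and a lumped APS pathway + ATP sulfurylase
performing substrate-level phosphorylation during sulfite oxidation. Every
non-boundary reaction is element- and charge-balanced (verified at build
time) and the closed network is EGC-free (verified by test).

Quantities the source literature leaves open are fixed once at textbook
values and isolated in the reaction table: 6/4/2 H+ translocated per quinol
at the aa3/bo3/bd oxidases, 4 H+ per ATP at the synthase (3 translocated + 1
chemical), 4 H+ pumped per NADH at complex I (run in reverse as the uphill
pathway), soluble transhydrogenase for NADPH, and an irreversible
periplasm→cytoplasm proton leak that lets surplus proton-motive force
dissipate. CO2 fixation is a full CBB cycle in two builds: *incomplete*
(SEBP-lacking, regenerating sedoheptulose-7-phosphate through the
transaldolase-type EC 2.2.1.2 bypass) and *classical* (SBP aldolase +
SBPase); the builds differ by exactly that switch. In this core both
variants happen to have identical ATP/NADPH demand per triose, so their
optima coincide — the comparison function is exercised for structural
consistency against direct LP, not for a growth gap, which in the original
organism-scale analysis arises from genome-scale context the core does not
carry. Biomass is deliberately minimal — one glyceraldehyde-3-phosphate plus
20 ATP of GAM, NGAM zero — keeping every reported rate exactly linear
(homogeneous) in the sulfur uptake. The core therefore reproduces pathway
*topologies and their ranking*, not the absolute fluxes of any deposited
genome-scale reconstruction; with the default 1.5 mmol/gDW/h sulfur uptake
it yields five pathways with ATP rates 7.5, 6.375, 6.0, 4.125 and
3.0 mmol/gDW/h, the top one being the OMP→SQR→condensation→TST/HDR→APS/SAT
route.

"ATP production rate" is the optimum of an ATP-hydrolysis sink
(ATP + H2O → ADP + Pi + H+), never a plain ATP demand, which would strand
the adenylate pool. The "NAD(P)H production rate" is a separate optimization
maximizing the summed flux of NADH and NADPH re-oxidation probes with equal
weight at the same medium (how the original analysis combined the two
cofactors is not documented; this definition is the package's choice and is
stated wherever the number is reported). CO2 uptake and growth come from
biomass maximization, with pFBA picking the representative flux vector.

Alternative pathways are enumerated by closing, one at a time, each reaction
of the current optimum's active sulfur set (sorted order), re-solving, and
recursing to at most two simultaneous closures; distinct active sets are
deduplicated and ranked by descending ATP rate. The depth cap terminates the
recursion while still realizing every alternative the core supports;
closures that leave no ATP production are discarded rather than reported as
zero-rate pathways.

During all sulfur simulations the competing electron-donor exchanges
(sulfide, thiosulfate, tetrathionate) are closed for uptake while CO2, O2,
water, protons, phosphate and sulfate export stay open. Substrate
equivalence converts a molecule uptake rate to sulfur-atom equivalents by
direct multiplication (tetrathionate carries 4 S). The fixed-CO2 substrate
demand is two-stage: maximize growth with CO2 uptake pinned, then minimize
substrate uptake with growth pinned at that optimum. The sor
(sulfur-oxygenase-reductase) insertion probe adds the balanced reaction
4 H2O + O2 + 4 S → 4 H+ + 2 SO3^2- + 2 H2S to the model; in the core its
cytoplasmic H2S product has no consumer, so the insertion is exactly
growth-neutral, mirroring the no-effect observation in the organism-scale
analysis.

## Synthetic fixtures and what passing tests show

All ground-truth fixtures come from `sulfurgem.synth`, seeded with numpy's
PCG64 so identical specs are bit-identical. The toy model is a linear
substrate→precursor chain plus an energy reaction (2 ATP per substrate) and
a biomass with configurable GAM, giving the closed-form optimum
uptake/(1 + GAM/2) used as an analytic oracle. Seeded EGCs are reversible
loops whose ATP step is written in the consuming direction, so running the
loop backwards nets ATP and a reference marking that step "forward" repairs
it. Seeded gaps are removals re-sampled until growth is provably zero.
Synthetic panels draw OU values from bands (20–100 / 130–300) that never
straddle the 114 threshold unless label noise is requested.

These fixtures exercise the algorithms' contracts — detection exactness,
repair termination and cleanliness, gap-fill recovery and cost bounds,
concordance arithmetic — on networks where the truth is known by
construction. They are small and noiseless by design: passing them shows the
machinery is correct, not that any particular genome-scale reconstruction is
accurate; organism-scale numbers depend on the deposited model's
stoichiometry, which is not bundled.

## Numerical and design choices

- Default bounds: reversible (−1000, 1000), irreversible (0, 1000);
  exchange flux < 0 is uptake. Boundary ids are `EX_`/`DM_`/`SK_` + metabolite.
- Bundled fixtures use readable BiGG-style identifiers (`atp_c`, `so3_c`);
  arbitrary id namespaces, including ModelSEED's, are accepted everywhere.
- EGC detection closes uptake but leaves secretion open: a genuine EGC is
  internal, and closing secretion would mask cycles that vent by-products.
- Repair ordering (currency order, sorted ids, first sanctioned restriction)
  trades optimality for reproducibility; the repair-minimality guarantee is
  deliberately weak (every change belonged to some detected cycle).
- `flux_range` on degenerate optima brackets each flux with two LPs at the
  pinned objective.
- The acceptance script derives all stochastic-suite seeds from its `--seed`
  via PCG64 and reports per-quantity problem sizes; suite sizes (20 seeds for
  repair/gap-fill, 2 networks for the vertex oracle, 10-well panels) keep
  the whole run within seconds while exercising each property.

## Known limitations

- Gap-filling is the LP relaxation, not MILP-minimal.
- The core's respiratory stoichiometry is fixed, not fitted; absolute ATP
  yields shift with the chosen H+/ATP and H+/quinol ratios.
- The bundled Biolog panel reproduces marginal counts only.
- No thermodynamic (ΔG) direction assignment, kinetic modelling, gene
  deletion analysis, or iron/nitrogen metabolism.
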