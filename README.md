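# sulfurgem

Curation and flux analysis of genome-scale metabolic models (GEMs) for
chemolithotrophic sulfur-oxidizing bacteria.

Sulfur oxidizers of the *Acidithiobacillus* type earn their living by
stripping electrons from inorganic sulfur — elemental S⁰, sulfide,
thiosulfate, tetrathionate — and spending the resulting proton-motive force
on ATP, on reverse (uphill) electron flow to NAD(P)⁺, and ultimately on CO₂
fixation through the Calvin–Benson–Bassham cycle. Which of several
intertwined sulfur-oxidation routes a strain actually uses, and what each
route is worth energetically, is hard to read off a genome. Constraint-based
modelling answers it quantitatively: given a stoichiometric network S, flux
balance analysis (FBA) solves

    max c·v   subject to   S·v = 0,   lb ≤ v ≤ ub,

and parsimonious FBA (pFBA) then minimizes Σ|vᵢ| at the pinned optimum, so
the surviving flux support *is* the predicted pathway.

`sulfurgem` packages the full workflow that takes two raw annotation-derived
draft reconstructions to an analysis-ready model, for modellers working on
sulfur oxidizers (or any awkward chemolithotroph):

- **model_core / io** — typed models (metabolites with formulas and charges,
  reactions with bounds and gene rules) with exact round-trips through COBRA
  JSON, SBML Level 3 + fbc, and a plain TSV dialect; element/charge balance
  checking; boundary-reaction helpers.
- **fba** — FBA, pFBA, flux ranges and yields on SciPy's HiGHS solver.
- **curation** — draft merging; detection and reference-guided repair of
  energy-generating cycles (loops that mint ATP from nothing and wreck every
  downstream yield); biomass installation with GAM/NGAM maintenance;
  precursor producibility checks; weight-added parsimonious (LP) gap-filling
  against a universal reaction database.
- **phenotype** — Biolog GEN III concordance: OU-thresholded calls
  (positive iff OU > 114), per-substrate growth simulation, TP/TN/FP/FN
  tables, and database-driven model extension for false negatives.
- **sulfur** — a bundled, element- and charge-balanced sulfur-oxidation core
  network (OMP, SQR, SDO, TQO, TetH, Sox, TST/HDR, APS/SAT, three terminal
  oxidases, uphill NADH dehydrogenase, CBB in SEBP-lacking and classical
  variants); ATP-maximal pathway prediction; alternative-pathway enumeration
  by iterative reaction closing; pathway energetics; substrate equivalence
  and fixed-CO₂ substrate-demand analyses.
- **synth** — seeded generators for every ground-truth fixture the tests
  use (toy models, seeded energy cycles and gaps, phenotype panels, split
  drafts).
- **pipeline / cli** — the end-to-end staged workflow and the `sulfurgem`
  command (`merge`, `fix-energy`, `gapfill`, `biolog`, `sulfur-paths`,
  `run-all`, `stats`, `synth`).

## Worked example

Enumerate the sulfur-oxidation pathways of the bundled core at the standard
sulfur uptake of 1.5 mmol/gDW/h:

```sh
$ sulfurgem sulfur-paths --rate 1.5
pathway           active_reactions  nadh_nadph_rate  atp_rate  co2_uptake  growth_rate
      I   APSSAT;CONDS;HDR;OMP;SQR            2.500     7.500    0.511364     0.170455
     II      CONDS;HDR;OMP;SOX;SQR            2.125     6.375    0.434659     0.144886
    III CONDS;HDR;OMP;SQR;TETH;TQO            2.000     6.000    0.409091     0.136364
     IV      CONDS;OMP;SDO;SOX;SQR            1.375     4.125    0.281250     0.093750
      V         APSSAT;OMP;SDO;SQR            1.000     3.000    0.204545     0.068182
```

Reading the table: the optimal route (pathway I) activates sulfur via the
outer-membrane proteins (OMP), oxidizes sulfide with SQR, condenses S⁰ with
sulfite to thiosulfate, re-oxidizes it through the rhodanese/Hdr-like lump
(TST/HDR), and finishes with the APS pathway's substrate-level
phosphorylation — every sulfur electron reaches the quinone pool, yielding
7.5 mmol ATP, 2.5 mmol NAD(P)H and 0.51 mmol fixed CO₂ per gDW·h at growth
rate 0.17 h⁻¹. Alternatives that divert electrons into the Sox system, the
TQO/TetH loop, or the oxygen-wasting dioxygenase (SDO) rank strictly lower.
Rates are exactly proportional to sulfur uptake (LP homogeneity), so the
ratios, rankings and topologies are the robust content; absolute values
depend on the documented textbook proton stoichiometries in
`src/sulfurgem/data/sulfur_core.reactions.tsv`.

The same analysis runs on any model file:
`sulfurgem sulfur-paths --model my_model.json --rate 1.5`. See
`docs/methods.md` for the science and every numerical choice.

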