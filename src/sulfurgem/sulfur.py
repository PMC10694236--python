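"""Sulfur-oxidation pathway prediction, enumeration and energetics.

The analysis asks, for a chemolithotrophic sulfur oxidizer: with elemental
sulfur as the only energy source (uptake fixed, every competing electron
donor closed), which set of sulfur-oxidation reactions maximizes the ATP
production rate?  The optimal pathway is the parsimonious-FBA support of
that optimization restricted to the sulfur-oxidation subsystem; alternative
pathways are enumerated by iteratively closing one reaction of the current
optimum and re-solving, collecting distinct active sets ranked by ATP rate.
Each pathway's energetics are reported as the standard four-column summary:
NAD(P)H production rate, ATP production rate, CO2 uptake rate, growth rate —
all computed at the same fixed sulfur uptake, so by LP homogeneity they
scale linearly in the uptake rate.

The module also bundles a small compartmentalized core network (see
``data/sulfur_core.reactions.tsv``) whose stoichiometry is element- and
charge-balanced and whose respiratory proton counts are documented textbook
values; it reproduces the pathway topologies and their ordering, not the
absolute fluxes of any particular genome-scale reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import MetabolicModel, Metabolite, Reaction, check_balance
from .fba import Medium, Objective, ZERO_TOL, atp_demand_id, fba, pfba
from .io import parse_equation

SULFUR_SUBSYSTEM = "Sulfur oxidation"
SULFUR_UPTAKE_DEFAULT = 1.5  # mmol/gDW/h
SULFUR_EXCHANGE = "EX_s_e"
#: competing energy-source exchanges closed during sulfur simulations
ENERGY_EXCHANGES = ("EX_s_e", "EX_h2s_e", "EX_s2o3_e", "EX_s4o6_e")


class CoreBuildError(ValueError):
    """The core spec contains an unbalanced or inconsistent entry."""


@dataclass(frozen=True)
class PathwayEnergetics:
    """Rates in mmol/gDW/h (growth in 1/h) at a fixed sulfur uptake."""

    atp_rate: float
    nadh_nadph_rate: float
    co2_uptake: float
    growth_rate: float
    sulfur_uptake: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.nadh_nadph_rate, self.atp_rate, self.co2_uptake, self.growth_rate)


@dataclass
class SulfurPathway:
    label: str
    active_reactions: tuple[str, ...]  # sulfur-subsystem support, sorted
    energetics: PathwayEnergetics
    closed_reactions: tuple[str, ...] = ()

    @property
    def active_set(self) -> frozenset[str]:
        return frozenset(self.active_reactions)


# -- bundled core -------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("sulfurgem").joinpath("data", name))


def build_sulfur_core(cbb_variant: str = "incomplete") -> MetabolicModel:
    """Build the bundled sulfur-oxidation core model.

    ``cbb_variant`` selects the CBB regeneration route: ``incomplete``
    (SEBP-lacking, transaldolase bypass) or ``classical`` (SBP aldolase +
    SBPase).  The build validates element/charge balance of every
    non-boundary reaction.
    """
    if cbb_variant not in ("incomplete", "classical"):
        raise ValueError(f"unknown CBB variant {cbb_variant!r}")
    model = MetabolicModel(f"sulfur_core_{cbb_variant}")
    mets = pd.read_csv(_data_path("sulfur_core.metabolites.tsv"), sep="\t", comment="#",
                       dtype=str).fillna("")
    for row in mets.itertuples(index=False):
        model.add_metabolite(
            Metabolite(row.id, name=row.name, formula=row.formula,
                       charge=int(row.charge), compartment=row.compartment)
        )
    rxns = pd.read_csv(_data_path("sulfur_core.reactions.tsv"), sep="\t", comment="#",
                       dtype=str).fillna("")
    for row in rxns.itertuples(index=False):
        if row.variant and row.variant != cbb_variant:
            continue
        stoich, _ = parse_equation(row.equation)
        rxn = Reaction(row.id, stoich, lower_bound=float(row.lb), upper_bound=float(row.ub),
                       gene_rule=row.gene_rule, subsystem=row.subsystem)
        model.add_reaction(rxn, allow_new_metabolites=False)
        imbalance = check_balance(rxn, model.metabolites)
        if isinstance(imbalance, dict) and imbalance:
            raise CoreBuildError(f"core reaction {rxn.id} unbalanced: {imbalance}")
    model.set_objective("BIOMASS")
    model.validate()
    return model


def core_medium(sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
                substrate_exchange: str = SULFUR_EXCHANGE) -> Medium:
    """Sulfur (or another RISC) as sole energy source; CO2/O2/salts open."""
    return Medium(
        uptake_limits={substrate_exchange: sulfur_rate},
        closed=set(ENERGY_EXCHANGES) - {substrate_exchange},
    )


def sulfur_reactions(model: MetabolicModel) -> list[str]:
    return [r.id for r in model.reactions.values() if r.subsystem == SULFUR_SUBSYSTEM]


# -- pathway prediction -------------------------------------------------------


def optimal_pathway(
    model: MetabolicModel,
    sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
    label: str = "I",
    closed: tuple[str, ...] = (),
) -> SulfurPathway | None:
    """ATP-maximal sulfur-oxidation pathway at a fixed sulfur uptake.

    Returns None when no ATP can be produced under the given closures.
    """
    work = model.copy()
    atp_rxn = atp_demand_id(work)
    for rid in closed:
        work.reactions[rid].lower_bound = 0.0
        work.reactions[rid].upper_bound = 0.0
    medium = core_medium(sulfur_rate)
    state = pfba(work, atp_rxn, medium)
    if not state.optimal:
        return None
    atp = fba(work, atp_rxn, medium).objective_value
    if atp <= ZERO_TOL:
        return None
    active = tuple(sorted(set(sulfur_reactions(work)) & state.support()))
    energetics = pathway_energetics(model, active, sulfur_rate, closed=closed)
    return SulfurPathway(label, active, energetics, closed_reactions=tuple(closed))


def pathway_energetics(
    model: MetabolicModel,
    active_reactions: tuple[str, ...],
    sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
    closed: tuple[str, ...] = (),
) -> PathwayEnergetics:
    """Energetics of a pathway: ATP, NAD(P)H, CO2 uptake and growth rates.

    Sulfur-subsystem reactions outside the active set are closed, then each
    quantity is a separate optimization at the same sulfur uptake: ATP and
    NAD(P)H as dissipation-probe optima (the NAD(P)H probe drains NADH and
    NADPH with equal weight), CO2 uptake and growth from biomass
    maximization.
    """
    work = model.copy()
    atp_rxn = atp_demand_id(work)
    inactive = (set(sulfur_reactions(work)) - set(active_reactions)) | set(closed)
    for rid in inactive:
        work.reactions[rid].lower_bound = 0.0
        work.reactions[rid].upper_bound = 0.0
    medium = core_medium(sulfur_rate)

    atp_state = fba(work, atp_rxn, medium)
    if not atp_state.optimal:
        raise ValueError(f"infeasible closure combination: {sorted(inactive)}")
    atp = max(0.0, atp_state.objective_value)

    nadh_nadph = 0.0
    probes = {}
    probe_model = work.copy()
    for name, stoich in (
        ("NADH_PROBE", {"nadh_c": -1.0, "nad_c": 1.0, "h_c": 1.0}),
        ("NADPH_PROBE", {"nadph_c": -1.0, "nadp_c": 1.0, "h_c": 1.0}),
    ):
        if all(m in probe_model.metabolites for m in stoich):
            probe_model.add_reaction(Reaction(name, stoich, lower_bound=0.0, upper_bound=1000.0))
            probes[name] = 1.0
    if probes:
        state = fba(probe_model, Objective(probes, "maximize"), medium)
        if state.optimal:
            nadh_nadph = max(0.0, state.objective_value)

    growth = co2 = 0.0
    if model.objective is not None:
        gstate = pfba(work, model.objective[0], medium)
        if gstate.optimal:
            growth = max(0.0, fba(work, model.objective[0], medium).objective_value)
            co2_ex = "EX_co2_e"
            if co2_ex in gstate.fluxes:
                co2 = max(0.0, -gstate.fluxes[co2_ex])
    return PathwayEnergetics(
        atp_rate=atp, nadh_nadph_rate=nadh_nadph, co2_uptake=co2,
        growth_rate=growth, sulfur_uptake=sulfur_rate,
    )


def enumerate_pathways(
    model: MetabolicModel,
    sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
    max_depth: int = 2,
) -> list[SulfurPathway]:
    """Alternative sulfur-oxidation pathways by iterative reaction closing.

    Starting from the ATP-optimal pathway, each reaction in the current
    optimum's active sulfur set is closed in turn (sorted id order) and the
    optimization re-run; distinct active sets are collected, recursion is
    capped at ``max_depth`` simultaneous closures, and the result is ranked
    by descending ATP rate.  Deterministic for a fixed model.
    """
    first = optimal_pathway(model, sulfur_rate)
    if first is None:
        return []
    seen: dict[frozenset[str], SulfurPathway] = {first.active_set: first}
    frontier = [first]
    for _ in range(max_depth):
        nxt: list[SulfurPathway] = []
        for pw in frontier:
            for rid in pw.active_reactions:
                closed = tuple(sorted(set(pw.closed_reactions) | {rid}))
                alt = optimal_pathway(model, sulfur_rate, closed=closed)
                if alt is None or alt.active_set in seen:
                    continue
                seen[alt.active_set] = alt
                nxt.append(alt)
        frontier = nxt
    ranked = sorted(seen.values(), key=lambda p: (-p.energetics.atp_rate, p.active_reactions))
    labels = ["I", "II", "III", "IV", "V"]
    for i, pw in enumerate(ranked):
        pw.label = labels[i] if i < len(labels) else str(i + 1)
    return ranked


# -- comparative analyses -----------------------------------------------------


def compare_cbb_variants(
    sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
    builder=build_sulfur_core,
) -> list[dict]:
    """Biomass maximization under each CBB variant, other settings identical."""
    rows = []
    for variant in ("classical", "incomplete"):
        try:
            model = builder(cbb_variant=variant)
        except Exception as exc:
            rows.append({"variant": variant, "co2_fixation": None, "growth": None,
                         "error": str(exc)})
            continue
        medium = core_medium(sulfur_rate)
        state = pfba(model, model.objective[0], medium)
        growth = fba(model, model.objective[0], medium).objective_value if state.optimal else 0.0
        co2 = max(0.0, -state.fluxes.get("EX_co2_e", 0.0)) if state.optimal else 0.0
        rows.append({"variant": variant, "co2_fixation": co2, "growth": growth})
    return rows


def substrate_equivalence(uptake_rate: float, sulfur_atoms_per_molecule: float) -> float:
    """Sulfur-equivalent uptake: molecules/h times S atoms per molecule."""
    if uptake_rate < 0 or sulfur_atoms_per_molecule < 0:
        raise ValueError("inputs must be non-negative")
    return uptake_rate * sulfur_atoms_per_molecule


def fixed_co2_substrate_demand(
    model: MetabolicModel,
    substrate_exchange: str,
    co2_rate: float,
) -> float:
    """Minimal substrate uptake sustaining a fixed CO2 uptake rate.

    Two-stage: growth is maximized with CO2 uptake fixed at ``co2_rate`` and
    the substrate unboundedly available, then with growth fixed at that
    optimum the substrate uptake is minimized.
    """
    work = model.copy()
    if substrate_exchange not in work.reactions:
        raise KeyError(f"no exchange {substrate_exchange}")
    for ex in ENERGY_EXCHANGES:
        if ex in work.reactions and ex != substrate_exchange:
            work.reactions[ex].lower_bound = 0.0
    work.reactions[substrate_exchange].lower_bound = -1000.0
    co2_ex = work.reactions["EX_co2_e"]
    co2_ex.lower_bound = co2_ex.upper_bound = -co2_rate
    if work.objective is None:
        raise ValueError("model has no growth objective")
    gstate = fba(work, work.objective[0])
    if not gstate.optimal:
        raise ValueError(f"infeasible at CO2 uptake {co2_rate}")
    growth_rxn = work.reactions[work.objective[0]]
    growth_rxn.lower_bound = growth_rxn.upper_bound = gstate.objective_value
    state = fba(work, Objective({substrate_exchange: 1.0}, "maximize"))
    if not state.optimal:
        raise ValueError("substrate minimization infeasible")
    return max(0.0, -state.objective_value)


def insertion_test(
    model: MetabolicModel,
    reaction: Reaction,
    sulfur_rate: float = SULFUR_UPTAKE_DEFAULT,
) -> tuple[float, float]:
    """Growth optimum before and after adding one reaction to the model."""
    medium = core_medium(sulfur_rate)
    if model.objective is None:
        raise ValueError("model has no growth objective")
    before = fba(model, model.objective[0], medium).objective_value
    work = model.copy()
    work.add_reaction(reaction.copy())
    after = fba(work, work.objective[0], medium).objective_value
    return before, after


#: the sor reaction the study strain lacks (sulfur oxygenase reductase),
#: written with the strain's compartment convention; cytoplasmic H2S has no
#: consumer in the core, mirroring the published no-growth-effect insertion.
def sor_reaction(model: MetabolicModel) -> Reaction:
    if "h2s_c" not in model.metabolites:
        model.add_metabolite(Metabolite("h2s_c", name="Hydrogen sulfide (cytoplasm)",
                                        formula="H2S", charge=0, compartment="c"))
    return Reaction(
        "SOR",
        {"h2o_c": -4, "o2_c": -1, "s_c": -4, "h_c": 4, "so3_c": 2, "h2s_c": 2},
        name="sulfur oxygenase reductase",
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem=SULFUR_SUBSYSTEM,
    )
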