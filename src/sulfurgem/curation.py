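"""Draft-model curation: merging, energy-cycle repair, biomass, gap-filling.

The curation workflow for a chemolithotroph draft reconstruction runs in
four stages, each of which is a function here:

1. :func:`merge_models` — union of two annotation-derived drafts.
2. :func:`detect_energy_cycles` / :func:`repair_energy_cycles` — find and
   eliminate energy-generating cycles (EGCs): thermodynamically infeasible
   loops that net-produce ATP or another energy currency with every exchange
   closed.  Repair restricts reaction reversibility guided by a
   directionality reference (e.g. MetaCyc-derived directions).
3. :func:`install_biomass` / :func:`check_precursors` — add a biomass
   reaction with growth-associated (GAM) and non-growth-associated (NGAM)
   ATP maintenance, and test each precursor for producibility.
4. :func:`gapfill` — weight-added parsimonious gap-filling: one LP over the
   union of the model and a universal reaction database that minimizes the
   weighted absolute flux through database reactions subject to a minimum
   target flux.  Model reactions carry weight zero, so only genuinely needed
   database reactions appear in the solution (parsimonious in the LP sense;
   a MILP could be smaller in pathological cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import FluxState, MetabolicModel, Reaction
from .fba import FEASIBILITY_TOL, ZERO_TOL, Medium, ensure_demand, fba, pfba

GAPFILL_THRESHOLD = 0.05  # mmol/gDW/h minimum target flux after filling


class MergeConflictError(ValueError):
    """Same reaction id with different stoichiometry in the two parents."""


class UnresolvedCycleError(RuntimeError):
    """An energy-generating cycle has no reference-sanctioned restriction."""


class GapfillError(RuntimeError):
    """The target stays infeasible even with the full universal database."""


@dataclass
class UniversalReactionDB:
    """Reaction templates with penalty weights for gap-filling."""

    reactions: dict[str, Reaction]
    weights: dict[str, float] = field(default_factory=dict)

    def weight(self, rxn_id: str) -> float:
        return self.weights.get(rxn_id, 1.0)

    @classmethod
    def from_tsv(cls, path) -> "UniversalReactionDB":
        import pandas as pd

        from .io import parse_equation

        table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        reactions, weights = {}, {}
        for row in table.itertuples(index=False):
            stoich, reversible = parse_equation(row.equation)
            lb = float(row.lb) if getattr(row, "lb", "") != "" else (-1000.0 if reversible else 0.0)
            ub = float(row.ub) if getattr(row, "ub", "") != "" else 1000.0
            reactions[row.id] = Reaction(
                row.id, stoich, lower_bound=lb, upper_bound=ub,
                subsystem=getattr(row, "subsystem", ""),
            )
            if getattr(row, "weight", "") != "":
                weights[row.id] = float(row.weight)
        return cls(reactions, weights)


@dataclass
class DirectionalityReference:
    """Allowed direction per reaction id: forward, reverse or reversible."""

    directions: dict[str, str]

    def __post_init__(self) -> None:
        bad = {d for d in self.directions.values()} - {"forward", "reverse", "reversible"}
        if bad:
            raise ValueError(f"unknown directions {bad}")

    @classmethod
    def from_tsv(cls, path) -> "DirectionalityReference":
        import pandas as pd

        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(dict(zip(table["reaction_id"], table["direction"])))


@dataclass
class BiomassComposition:
    """Precursor demands (mmol/gDW) plus GAM/NGAM ATP maintenance costs."""

    precursors: dict[str, float]
    gam: float = 0.0  # mmol ATP per gDW, hydrolyzed in the biomass reaction
    ngam: float = 0.0  # mmol ATP/gDW/h, enforced as an always-on maintenance flux

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.precursors.values()):
            raise ValueError("precursor demands must be positive")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM/NGAM must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "BiomassComposition":
        import pandas as pd

        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        gam = ngam = 0.0
        precursors: dict[str, float] = {}
        for row in table.itertuples(index=False):
            if row.metabolite_id == "GAM":
                gam = float(row.demand)
            elif row.metabolite_id == "NGAM":
                ngam = float(row.demand)
            else:
                precursors[row.metabolite_id] = float(row.demand)
        return cls(precursors, gam=gam, ngam=ngam)


@dataclass
class CurationReport:
    """Ledger of the changes one curation stage made to a model."""

    stage: str
    modified_reversibilities: list[tuple[str, tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    added_reactions: list[str] = field(default_factory=list)
    added_metabolites: list[str] = field(default_factory=list)
    precursor_status: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "modified_reversibilities": [
                {"reaction": r, "old_bounds": list(old), "new_bounds": list(new)}
                for r, old, new in self.modified_reversibilities
            ],
            "added_reactions": self.added_reactions,
            "added_metabolites": self.added_metabolites,
            "precursor_status": self.precursor_status,
            "notes": self.notes,
        }


# -- stage 1: merge -----------------------------------------------------------


def merge_models(a: MetabolicModel, b: MetabolicModel) -> tuple[MetabolicModel, CurationReport]:
    """Union of two draft models by id.

    Shared reactions must have identical stoichiometry (else
    :class:`MergeConflictError`); differing bounds are merged to the union of
    allowed directions and logged; gene rules are merged by OR.
    """
    report = CurationReport(stage="merge")
    merged = a.copy()
    merged.id = f"{a.id}+{b.id}"
    for met in b.metabolites.values():
        if met.id not in merged.metabolites:
            merged.add_metabolite(met.copy())
            report.added_metabolites.append(met.id)
    for rxn in b.reactions.values():
        if rxn.id not in merged.reactions:
            merged.add_reaction(rxn.copy(), allow_new_metabolites=False)
            report.added_reactions.append(rxn.id)
            continue
        mine = merged.reactions[rxn.id]
        if not _same_stoichiometry(mine.stoichiometry, rxn.stoichiometry):
            from .io import format_equation

            raise MergeConflictError(
                f"reaction {rxn.id} differs between parents:\n"
                f"  {a.id}: {format_equation(mine)}\n"
                f"  {b.id}: {format_equation(rxn)}"
            )
        lb = min(mine.lower_bound, rxn.lower_bound)
        ub = max(mine.upper_bound, rxn.upper_bound)
        if (lb, ub) != (mine.lower_bound, mine.upper_bound):
            report.modified_reversibilities.append(
                (rxn.id, (mine.lower_bound, mine.upper_bound), (lb, ub))
            )
            mine.lower_bound, mine.upper_bound = lb, ub
        if rxn.gene_rule and rxn.gene_rule != mine.gene_rule:
            mine.gene_rule = (
                f"({mine.gene_rule}) or ({rxn.gene_rule})" if mine.gene_rule else rxn.gene_rule
            )
    if merged.objective is None and b.objective is not None:
        merged.objective = b.objective
    return merged, report


def _same_stoichiometry(x: dict[str, float], y: dict[str, float], tol: float = 1e-9) -> bool:
    return set(x) == set(y) and all(abs(x[k] - y[k]) <= tol for k in x)


# -- stage 2: energy-generating cycles ---------------------------------------

#: energy currencies audited for net production with all exchanges closed.
#: Each maps currency name -> dissipation-reaction stoichiometry; a currency
#: is only tested when all of its metabolites exist in the model.  The set
#: (ATP, GTP, NAD(P)H, FADH2, quinol, proton-motive force) is the community-
#: standard audit and subsumes the plain no-substrate ATP check.
DEFAULT_CURRENCIES: dict[str, dict[str, float]] = {
    "ATP": {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
    "GTP": {"gtp_c": -1, "h2o_c": -1, "gdp_c": 1, "pi_c": 1, "h_c": 1},
    "NADH": {"nadh_c": -1, "nad_c": 1, "h_c": 1},
    "NADPH": {"nadph_c": -1, "nadp_c": 1, "h_c": 1},
    "FADH2": {"fadh2_c": -1, "fad_c": 1, "h_c": 2},
    "QH2": {"q8h2_c": -1, "q8_c": 1, "h_c": 2},
    "PMF": {"h_p": -1, "h_c": 1},
}


def close_all_exchanges(model: MetabolicModel) -> MetabolicModel:
    """Copy of the model with uptake blocked on every exchange reaction."""
    out = model.copy()
    for ex in out.exchanges:
        out.reactions[ex].lower_bound = max(0.0, out.reactions[ex].lower_bound)
    return out


def detect_energy_cycles(
    model: MetabolicModel,
    currencies: dict[str, dict[str, float]] | None = None,
) -> list[tuple[str, set[str]]]:
    """Energy-generating cycles, one entry per flagged currency.

    For each currency a dissipation demand is added to a fully closed model
    and maximized; a positive optimum (> 1e-6) flags the currency, and the
    parsimonious support of that optimum (minus the probe reaction itself)
    is returned as the offending cycle.  An empty list means clean.
    """
    currencies = currencies if currencies is not None else DEFAULT_CURRENCIES
    closed = close_all_exchanges(model)
    found: list[tuple[str, set[str]]] = []
    for name, stoich in currencies.items():
        if not all(m in closed.metabolites for m in stoich):
            continue
        probe = closed.copy()
        probe_id = f"EGC_PROBE_{name}"
        probe.add_reaction(
            Reaction(probe_id, dict(stoich), lower_bound=0.0, upper_bound=1000.0)
        )
        state = fba(probe, probe_id)
        if state.optimal and state.objective_value > ZERO_TOL:
            par = pfba(probe, probe_id)
            cycle = par.support() - {probe_id} if par.optimal else state.support() - {probe_id}
            found.append((name, cycle))
    return found


def repair_energy_cycles(
    model: MetabolicModel,
    reference: DirectionalityReference,
    currencies: dict[str, dict[str, float]] | None = None,
    max_iterations: int = 500,
) -> tuple[MetabolicModel, CurationReport]:
    """Restrict reaction reversibilities until every currency optimum is zero.

    Deterministic: cycles are processed in currency order, candidate
    reactions within a cycle in sorted id order, and the first restriction
    the reference sanctions (and that actually tightens a bound) is applied
    before re-detecting.
    """
    work = model.copy()
    report = CurationReport(stage="energy-cycle-repair")
    for _ in range(max_iterations):
        cycles = detect_energy_cycles(work, currencies)
        if not cycles:
            return work, report
        currency, cycle = cycles[0]
        applied = False
        for rxn_id in sorted(cycle):
            direction = reference.directions.get(rxn_id)
            if direction is None or direction == "reversible":
                continue
            rxn = work.reactions[rxn_id]
            old = (rxn.lower_bound, rxn.upper_bound)
            if direction == "forward":
                new = (max(0.0, rxn.lower_bound), rxn.upper_bound)
            else:  # reverse
                new = (rxn.lower_bound, min(0.0, rxn.upper_bound))
            if new == old:
                continue
            rxn.lower_bound, rxn.upper_bound = new
            report.modified_reversibilities.append((rxn_id, old, new))
            applied = True
            break
        if not applied:
            raise UnresolvedCycleError(
                f"{currency}-generating cycle has no reference-sanctioned member: "
                f"{sorted(cycle)}"
            )
    raise UnresolvedCycleError("repair did not converge within the iteration cap")


# -- stage 3: biomass ---------------------------------------------------------

BIOMASS_ID = "BIOMASS"
NGAM_ID = "ATPM_NGAM"


def install_biomass(
    model: MetabolicModel,
    composition: BiomassComposition,
) -> MetabolicModel:
    """Add a biomass reaction (precursors + GAM ATP) and an NGAM maintenance.

    Missing precursor metabolites are an error, never silently dropped.  The
    biomass reaction becomes the model objective.
    """
    missing = [m for m in composition.precursors if m not in model.metabolites]
    if missing:
        raise KeyError(f"precursor metabolites absent from model: {missing}")
    out = model.copy()
    stoich = {m: -d for m, d in composition.precursors.items()}
    if composition.gam > 0:
        for met, coef in (("atp_c", -1), ("h2o_c", -1), ("adp_c", 1), ("pi_c", 1), ("h_c", 1)):
            if met not in out.metabolites:
                raise KeyError(f"GAM requires metabolite {met}")
            stoich[met] = stoich.get(met, 0.0) + coef * composition.gam
    out.add_reaction(
        Reaction(BIOMASS_ID, stoich, name="biomass", lower_bound=0.0, upper_bound=1000.0,
                 subsystem="Biomass")
    )
    if composition.ngam > 0:
        out.add_reaction(
            Reaction(
                NGAM_ID,
                {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
                name="non-growth-associated maintenance",
                lower_bound=composition.ngam,
                upper_bound=composition.ngam,
                subsystem="Maintenance",
            )
        )
    out.set_objective(BIOMASS_ID)
    return out


def check_precursors(
    model: MetabolicModel,
    composition: BiomassComposition,
    medium: Medium | None = None,
) -> dict[str, str]:
    """Per-precursor producibility: FBA on a demand for each precursor.

    A precursor whose demand optimum is below 1e-6 under the growth medium is
    flagged ``blocked``; otherwise ``synthesizable``.
    """
    status: dict[str, str] = {}
    for met_id in composition.precursors:
        if met_id not in model.metabolites:
            status[met_id] = "blocked"
            continue
        probe = model.copy()
        demand = ensure_demand(probe, met_id)
        state = fba(probe, demand, medium)
        ok = state.optimal and state.objective_value > ZERO_TOL
        status[met_id] = "synthesizable" if ok else "blocked"
    return status


# -- stage 4: gap-filling -----------------------------------------------------


def gapfill(
    model: MetabolicModel,
    db: UniversalReactionDB,
    target: str,
    medium: Medium | None = None,
    threshold: float = GAPFILL_THRESHOLD,
) -> tuple[list[str], MetabolicModel]:
    """Weight-added parsimonious gap-filling.

    Solves one LP over the union of the model and the database that minimizes
    ``sum_i w_i |v_i|`` over database reactions subject to steady state and a
    target flux >= ``threshold``; model reactions carry weight zero.  Database
    reactions with |flux| > 1e-6 are added to the model.  Returns
    ``([], model)`` untouched when the target is already feasible.
    """
    base = medium.apply(model) if medium else model.copy()
    if target not in base.reactions:
        raise KeyError(f"target reaction {target} not in model")
    pre = fba(base, target)
    if pre.optimal and pre.objective_value >= threshold - FEASIBILITY_TOL:
        return [], model

    union = base.copy()
    candidates = []
    for rxn in db.reactions.values():
        if rxn.id in union.reactions:
            continue
        union.add_reaction(rxn.copy())
        candidates.append(rxn.id)
    # LP: split all columns, weight only db columns, target flux fixed >= threshold
    union.reactions[target].lower_bound = max(union.reactions[target].lower_bound, threshold)
    S = union.stoichiometric_matrix()
    n = S.shape[1]
    A = sparse.hstack([S, -S]).tocsr()
    lb = np.array([r.lower_bound for r in union.reactions.values()])
    ub = np.array([r.upper_bound for r in union.reactions.values()])
    bounds = [(max(0.0, l), max(0.0, u)) for l, u in zip(lb, ub)] + [
        (max(0.0, -u), max(0.0, -l)) for l, u in zip(lb, ub)
    ]
    weights = np.zeros(n)
    ids = list(union.reactions)
    for i, rid in enumerate(ids):
        if rid in set(candidates):
            weights[i] = db.weight(rid)
    res = linprog(
        np.concatenate([weights, weights]),
        A_eq=A,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    if res.status != 0:
        raise GapfillError(
            f"target {target} infeasible at flux {threshold} even with the full database"
        )
    net = res.x[:n] - res.x[n:]
    flux = dict(zip(ids, net))
    # an essential reaction may carry no more flux than the target threshold
    # itself, so the support cutoff must stay well below it
    added_tol = min(ZERO_TOL, threshold / 100.0)
    added = sorted(r for r in candidates if abs(flux[r]) > added_tol)
    filled = model.copy()
    for rid in added:
        filled.add_reaction(db.reactions[rid].copy())
    return added, filled
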