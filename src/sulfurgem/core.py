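"""Domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a compartmentalized stoichiometric network:
metabolites with elemental formulas and charges, reactions with flux bounds
(mmol/gDW/h) and boolean gene-association rules, and a designated objective
reaction.  The model is the object every curation and analysis stage of this
package transforms.

Conventions follow the COBRA community: default bounds are (-1000, 1000) for
reversible and (0, 1000) for irreversible reactions; for an exchange reaction
a negative flux means uptake and a positive flux means secretion; boundary
reaction ids are prefixed ``EX_`` (exchange), ``DM_`` (demand) and ``SK_``
(sink).  Metabolite ids carry a trailing ``_c``/``_p``/``_e`` compartment
suffix which must agree with the ``compartment`` field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

DEFAULT_UB = 1000.0
DEFAULT_LB = -1000.0

#: boundary-reaction prefixes and their conventional bounds
BOUNDARY_KINDS = {
    "exchange": ("EX_", (DEFAULT_LB, DEFAULT_UB)),
    "demand": ("DM_", (0.0, DEFAULT_UB)),
    "sink": ("SK_", (DEFAULT_LB, DEFAULT_UB)),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")
_GENE_TOKEN = re.compile(r"[^\s()]+")
_COMPARTMENT_SUFFIX = re.compile(r"_([a-z])$")


class ModelIntegrityError(ValueError):
    """A model (or file) violates a structural invariant."""


class FormatError(ValueError):
    """A file cannot be parsed in the named dialect."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int | None = None
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.compartment:
            m = _COMPARTMENT_SUFFIX.search(self.id)
            if m:
                self.compartment = m.group(1)

    def copy(self) -> "Metabolite":
        return replace(self)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_LB
    upper_bound: float = DEFAULT_UB
    gene_rule: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> set[str]:
        return parse_genes(self.gene_rule)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class FluxState:
    """Outcome of one linear-programming solve.

    ``fluxes`` maps reaction id to flux in mmol/gDW/h.  When ``status`` is
    ``"optimal"`` the flux vector satisfies S.v = 0 within solver tolerance
    and every flux lies within its bounds.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def support(self, zero_tol: float = 1e-6) -> set[str]:
        """Reaction ids carrying flux above the reported-zero threshold."""
        return {r for r, v in self.fluxes.items() if abs(v) > zero_tol}


@dataclass(frozen=True)
class ModelStats:
    n_genes: int
    n_metabolites: int
    n_reactions: int


class MetabolicModel:
    """A compartmentalized reaction network with bounds and an objective."""

    def __init__(self, model_id: str = "model", compartments: set[str] | None = None):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: tuple[str, str] | None = None  # (reaction id, sense)
        self.compartments: set[str] = set(compartments or ())

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        existing = self.metabolites.get(met.id)
        if existing is not None:
            return existing
        self.metabolites[met.id] = met
        if met.compartment:
            self.compartments.add(met.compartment)
        return met

    def add_reaction(self, rxn: Reaction, *, allow_new_metabolites: bool = True) -> Reaction:
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if not allow_new_metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
                self.add_metabolite(Metabolite(met_id))
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        rxn = self.reactions.pop(rxn_id)
        if self.objective and self.objective[0] == rxn_id:
            self.objective = None
        return rxn

    def set_objective(self, rxn_id: str, sense: str = "maximize") -> None:
        if rxn_id not in self.reactions:
            raise ModelIntegrityError(f"objective reaction {rxn_id} not in model")
        if sense not in ("maximize", "minimize"):
            raise ValueError(f"bad objective sense {sense!r}")
        self.objective = (rxn_id, sense)

    def copy(self) -> "MetabolicModel":
        out = MetabolicModel(self.id, set(self.compartments))
        out.metabolites = {k: m.copy() for k, m in self.metabolites.items()}
        out.reactions = {k: r.copy() for k, r in self.reactions.items()}
        out.objective = self.objective
        return out

    # -- queries -------------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    def is_boundary(self, rxn_id: str) -> bool:
        return len(self.reactions[rxn_id].stoichiometry) == 1

    def is_exchange(self, rxn_id: str) -> bool:
        rxn = self.reactions[rxn_id]
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolites[met_id].compartment == "e"

    @property
    def exchanges(self) -> list[str]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def stoichiometric_matrix(self, dense: bool = False):
        """S with one row per metabolite, one column per reaction (insertion order)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        S = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        ).tocsr()
        return S.toarray() if dense else S

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on any broken invariant."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelIntegrityError(f"reaction {rxn.id}: inverted bounds")
        for met in self.metabolites.values():
            m = _COMPARTMENT_SUFFIX.search(met.id)
            if m and met.compartment and m.group(1) != met.compartment:
                raise ModelIntegrityError(
                    f"metabolite {met.id}: id suffix disagrees with compartment "
                    f"{met.compartment!r}"
                )
        if self.objective is not None and self.objective[0] not in self.reactions:
            raise ModelIntegrityError(f"objective reaction {self.objective[0]} missing")

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# -- operations ---------------------------------------------------------------


def parse_genes(gene_rule: str) -> set[str]:
    """Distinct gene identifiers in a boolean gene-association expression."""
    if not gene_rule:
        return set()
    return {
        tok for tok in _GENE_TOKEN.findall(gene_rule) if tok.lower() not in ("and", "or")
    }


def model_stats(model: MetabolicModel) -> ModelStats:
    return ModelStats(
        n_genes=len(model.genes),
        n_metabolites=len(model.metabolites),
        n_reactions=len(model.reactions),
    )


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string like ``C10H12N5O13P3`` into counts.

    Raises :class:`ValueError` on strings that are not a plain element/count
    sequence (nested groups, charges, wildcards).
    """
    if formula is None:
        raise ValueError("no formula")
    formula = formula.strip()
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        element, num = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def check_balance(
    rxn: Reaction,
    metabolites: dict[str, Metabolite],
    tol: float = 1e-6,
) -> dict[str, float] | str:
    """Per-element and charge imbalance of a reaction.

    Returns a dict mapping element symbol (and ``"charge"``) to the net excess
    on the product side; an empty dict means balanced.  Boundary pseudo-
    reactions (single metabolite) and biomass reactions are exempt and report
    ``"exempt"``.  If any participant has an unparseable or missing formula
    the reaction reports ``"unknown"`` rather than failing.
    """
    if len(rxn.stoichiometry) == 1 or "biomass" in rxn.id.lower():
        return "exempt"
    balance: dict[str, float] = {}
    charge_known = True
    for met_id, coef in rxn.stoichiometry.items():
        met = metabolites.get(met_id)
        if met is None:
            return "unknown"
        try:
            counts = parse_formula(met.formula)
        except ValueError:
            return "unknown"
        for element, n in counts.items():
            balance[element] = balance.get(element, 0.0) + coef * n
        if met.charge is None:
            charge_known = False
        else:
            balance["charge"] = balance.get("charge", 0.0) + coef * met.charge
    if not charge_known:
        balance.pop("charge", None)
    return {k: v for k, v in balance.items() if abs(v) > tol}


def add_boundary(model: MetabolicModel, met_id: str, kind: str) -> MetabolicModel:
    """Add an exchange/demand/sink pseudo-reaction for one metabolite.

    Mutates and returns the model; adding the same boundary twice is a no-op.
    The reaction id is deterministic (``EX_<met>`` etc.).
    """
    if kind not in BOUNDARY_KINDS:
        raise ValueError(f"unknown boundary kind {kind!r}")
    if met_id not in model.metabolites:
        raise ModelIntegrityError(f"metabolite {met_id} not in model")
    prefix, bounds = BOUNDARY_KINDS[kind]
    if kind == "exchange" and model.metabolites[met_id].compartment != "e":
        raise ModelIntegrityError(
            f"exchange requires an extracellular metabolite, {met_id} is in "
            f"compartment {model.metabolites[met_id].compartment!r}"
        )
    rxn_id = prefix + met_id
    if rxn_id in model.reactions:
        return model
    model.add_reaction(
        Reaction(rxn_id, {met_id: -1.0}, name=f"{kind} {met_id}",
                 lower_bound=bounds[0], upper_bound=bounds[1], subsystem="Boundary")
    )
    return model
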