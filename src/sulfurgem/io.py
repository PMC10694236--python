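"""Readers and writers for the model formats the pipeline touches.

Three dialects are supported and round-trip exactly (ids, stoichiometric
coefficients, bounds, gene rules):

``json``
    The COBRA community JSON schema (``metabolites`` / ``reactions`` /
    ``genes`` arrays), so models exported by cobrapy load without conversion.
``sbml``
    SBML Level 3 with the ``fbc`` package for flux bounds and objectives.
    On read, legacy kinetic-law ``LOWER_BOUND``/``UPPER_BOUND`` parameters are
    also accepted, since deposited models predate fbc in some pipelines.
``tsv``
    A two-file table dialect: ``<stem>.reactions.tsv`` with columns
    id/equation/lb/ub/gene_rule/subsystem and ``<stem>.metabolites.tsv`` with
    id/name/formula/charge/compartment.  Equation grammar: ``A + 2 B => C``
    (irreversible), ``A <=> B`` (reversible); one side may be empty for
    boundary reactions; species carry compartment suffixes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .core import (
    DEFAULT_LB,
    DEFAULT_UB,
    FormatError,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
)

_ARROW = re.compile(r"<=>|=>|<--|-->|<->")


def read_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Read a model; the dialect is inferred from the suffix when omitted."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        model = _read_json(path)
    elif dialect == "sbml":
        model = _read_sbml(path)
    elif dialect == "tsv":
        model = _read_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> Path:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    model.validate()
    if dialect == "json":
        _write_json(model, path)
    elif dialect == "sbml":
        _write_sbml(model, path)
    elif dialect == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer dialect from {path.name!r}")


# -- COBRA JSON ---------------------------------------------------------------


def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    model = MetabolicModel(doc.get("id", path.stem))
    for mdoc in doc.get("metabolites", []):
        if "id" not in mdoc:
            raise FormatError(f"{path}: metabolite entry without id: {mdoc}")
        charge = mdoc.get("charge")
        model.add_metabolite(
            Metabolite(
                mdoc["id"],
                name=mdoc.get("name", ""),
                formula=mdoc.get("formula") or "",
                charge=int(charge) if charge is not None else None,
                compartment=mdoc.get("compartment", ""),
            )
        )
    objective = None
    for rdoc in doc.get("reactions", []):
        if "id" not in rdoc:
            raise FormatError(f"{path}: reaction entry without id: {rdoc}")
        stoich = {k: float(v) for k, v in rdoc.get("metabolites", {}).items()}
        for met_id in stoich:
            if met_id not in model.metabolites:
                raise ModelIntegrityError(
                    f"{path}: reaction {rdoc['id']} references undeclared "
                    f"metabolite {met_id}"
                )
        model.add_reaction(
            Reaction(
                rdoc["id"],
                stoich,
                name=rdoc.get("name", ""),
                lower_bound=float(rdoc.get("lower_bound", DEFAULT_LB)),
                upper_bound=float(rdoc.get("upper_bound", DEFAULT_UB)),
                gene_rule=rdoc.get("gene_reaction_rule", ""),
                subsystem=rdoc.get("subsystem", ""),
            ),
            allow_new_metabolites=False,
        )
        coef = rdoc.get("objective_coefficient", 0)
        if coef:
            objective = (rdoc["id"], "maximize" if coef > 0 else "minimize")
    if objective:
        model.set_objective(*objective)
    if "compartments" in doc:
        model.compartments |= set(doc["compartments"])
    return model


def _write_json(model: MetabolicModel, path: Path) -> None:
    obj_id = model.objective[0] if model.objective else None
    obj_coef = 0
    if model.objective:
        obj_coef = 1 if model.objective[1] == "maximize" else -1
    doc = {
        "id": model.id,
        "compartments": {c: c for c in sorted(model.compartments)},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_rule,
                "subsystem": r.subsystem,
                **({"objective_coefficient": obj_coef} if r.id == obj_id else {}),
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# -- TSV ----------------------------------------------------------------------


def _tsv_paths(path: Path) -> tuple[Path, Path]:
    """Map a stem (or either member file) to the reaction/metabolite pair."""
    name = path.name
    for tag in (".reactions.tsv", ".metabolites.tsv", ".tsv"):
        if name.endswith(tag):
            name = name[: -len(tag)]
            break
    base = path.with_name(name)
    return (
        base.with_name(base.name + ".reactions.tsv"),
        base.with_name(base.name + ".metabolites.tsv"),
    )


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A + 2 B => C"`` into (stoichiometry, reversible)."""
    m = _ARROW.search(equation)
    if not m:
        raise FormatError(f"no arrow in equation {equation!r}")
    arrow = m.group(0)
    reversible = arrow in ("<=>", "<->")
    lhs, rhs = equation[: m.start()], equation[m.end() :]
    stoich: dict[str, float] = {}

    def _side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise FormatError(f"bad coefficient in term {term!r}") from exc
                met = parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise FormatError(f"bad term {term!r} in equation {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    _side(lhs, -1.0)
    _side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise FormatError(f"equation {equation!r} has empty net stoichiometry")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    def _fmt(items):
        terms = []
        for met, coef in items:
            coef = abs(coef)
            terms.append(met if coef == 1 else f"{coef:g} {met}")
        return " + ".join(terms)

    lhs = _fmt((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    rhs = _fmt((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{lhs} {arrow} {rhs}".strip()


def _read_tsv(path: Path) -> MetabolicModel:
    rxn_path, met_path = _tsv_paths(path)
    if not rxn_path.exists():
        raise FormatError(f"missing reactions table {rxn_path}")
    model = MetabolicModel(rxn_path.name.replace(".reactions.tsv", ""))
    if met_path.exists():
        mets = pd.read_csv(met_path, sep="\t", comment="#", dtype=str).fillna("")
        for row in mets.itertuples(index=False):
            model.add_metabolite(
                Metabolite(
                    row.id,
                    name=getattr(row, "name", ""),
                    formula=getattr(row, "formula", ""),
                    charge=int(float(row.charge)) if getattr(row, "charge", "") != "" else None,
                    compartment=getattr(row, "compartment", ""),
                )
            )
    rxns = pd.read_csv(rxn_path, sep="\t", comment="#", dtype=str).fillna("")
    for row in rxns.itertuples(index=False):
        stoich, reversible = parse_equation(row.equation)
        lb = float(row.lb) if getattr(row, "lb", "") != "" else (DEFAULT_LB if reversible else 0.0)
        ub = float(row.ub) if getattr(row, "ub", "") != "" else DEFAULT_UB
        model.add_reaction(
            Reaction(
                row.id,
                stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=getattr(row, "gene_rule", ""),
                subsystem=getattr(row, "subsystem", ""),
            )
        )
    return model


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    rxn_path, met_path = _tsv_paths(path)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": format_equation(r),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ]
    ).to_csv(rxn_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": "" if m.charge is None else m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(met_path, sep="\t", index=False)


# -- SBML L3 + fbc ------------------------------------------------------------

# SBML ids must be SId; COBRA ids may start with digits or contain other
# characters, so we apply the conventional prefix/escape scheme.
def _sid(kind: str, raw: str) -> str:
    return kind + re.sub(r"[^A-Za-z0-9_]", "__", raw)


def _unsid(kind: str, sid: str) -> str:
    return sid[len(kind):] if sid.startswith(kind) else sid


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error: {err.getMessage() if err else 'unknown'}")
    smodel = doc.getModel()
    if smodel is None:
        raise FormatError(f"{path}: no <model> element")
    model = MetabolicModel(smodel.getId() or path.stem)
    for i in range(smodel.getNumCompartments()):
        model.compartments.add(smodel.getCompartment(i).getId())
    fbc = smodel.getPlugin("fbc")
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        charge = None
        formula = ""
        if sfbc is not None:
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                _unsid("M_", sp.getId()),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )
    params = {
        smodel.getParameter(i).getId(): smodel.getParameter(i).getValue()
        for i in range(smodel.getNumParameters())
    }
    obj_id, obj_sense = None, "maximize"
    if fbc is not None and fbc.getActiveObjective() is not None:
        active = fbc.getActiveObjective()
        obj_sense = "maximize" if active.getType() == "maximize" else "minimize"
        if active.getNumFluxObjectives() > 0:
            obj_id = _unsid("R_", active.getFluxObjective(0).getReaction())
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            met = _unsid("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            met = _unsid("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        lb, ub = None, None
        rfbc = srxn.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound())
        if lb is None or ub is None:
            # legacy dialect: bounds as kinetic-law local parameters
            kl = srxn.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND" and lb is None:
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND" and ub is None:
                        ub = p.getValue()
        reversible = srxn.getReversible()
        if lb is None:
            lb = DEFAULT_LB if reversible else 0.0
        if ub is None:
            ub = DEFAULT_UB
        gene_rule = ""
        if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            gene_rule = _association_to_rule(assoc, smodel)
        model.add_reaction(
            Reaction(
                _unsid("R_", srxn.getId()),
                stoich,
                name=srxn.getName(),
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_rule=gene_rule,
            )
        )
    if obj_id and obj_id in model.reactions:
        model.set_objective(obj_id, obj_sense)
    return model


def _association_to_rule(assoc, smodel) -> str:
    import libsbml

    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        gp = smodel.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() or gp.getId() if gp else assoc.getGeneProduct()
    op = " and " if assoc.isFbcAnd() else " or "
    parts = [
        _association_to_rule(assoc.getAssociation(i), smodel)
        for i in range(assoc.getNumAssociations())
    ]
    return "(" + op.join(p for p in parts if p) + ")"


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.id) or "model")
    mfbc = smodel.getPlugin("fbc")
    mfbc.setStrict(True)
    for comp in sorted(model.compartments) or ["c"]:
        c = smodel.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for met in model.metabolites.values():
        sp = smodel.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment or sorted(model.compartments)[0])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sfbc = sp.getPlugin("fbc")
        if met.charge is not None:
            sfbc.setCharge(met.charge)
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
    genes = sorted(model.genes)
    for g in genes:
        gp = mfbc.createGeneProduct()
        gp.setId(_sid("G_", g))
        gp.setLabel(g)
    bound_params: dict[float, str] = {}

    def _param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        srxn = smodel.createReaction()
        srxn.setId(_sid("R_", rxn.id))
        srxn.setName(rxn.name)
        srxn.setFast(False)
        srxn.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = srxn.createReactant() if coef < 0 else srxn.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = srxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(_param(rxn.upper_bound))
        if rxn.gene_rule:
            gpa = rfbc.createGeneProductAssociation()
            rule = re.sub(r"\b(and|or)\b", lambda m: m.group(1), rxn.gene_rule)
            for g in sorted(model.genes, key=len, reverse=True):
                rule = re.sub(rf"(?<![\w]){re.escape(g)}(?![\w])", _sid("G_", g), rule)
            gpa.setAssociation(rule, True, False)
    if model.objective:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType(model.objective[1])
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective[0]))
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))
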