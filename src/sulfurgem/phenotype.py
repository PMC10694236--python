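"""Biolog GEN III phenotype-array concordance.

A phenotype panel records, per carbon-source substrate, the OmniLog-unit (OU)
dye-reduction signal and a growth call.  Calls follow the strict threshold
rule: positive iff OU > 114 (the instrument's conventional cutoff); ambiguous
"boundary" wells are scored as negative but kept flagged.  Growth simulation
opens the substrate's exchange on top of a base medium and asks whether the
biomass optimum exceeds a strict positivity threshold; the confusion table
(TP/TN/FP/FN, agreement = 100*(TP+TN)/N) compares simulated and experimental
calls.  For a chemolithotroph the base medium keeps the inorganic energy
source available: a carbon source alone supports no energy metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .core import MetabolicModel, add_boundary
from .curation import CurationReport, UniversalReactionDB, gapfill
from .fba import ZERO_TOL, Medium, fba

OU_THRESHOLD = 114.0
TEST_UPTAKE = 10.0  # mmol substrate/gDW/h opened during a carbon-source test
GROWTH_THRESHOLD = 1e-6  # h^-1; strict positivity robust to solver noise


@dataclass
class PhenotypeEntry:
    substrate: str
    metabolite_id: str = "unmapped"  # model metabolite id, or "unmapped"
    ou: float = 0.0
    call: str = ""  # positive | negative | boundary
    model_call: str = ""  # simulated call, once computed
    reason: str = ""

    @property
    def experimental_positive(self) -> bool:
        # boundary wells are scored negative (flagged via the call field)
        return self.call == "positive"


@dataclass
class PhenotypePanel:
    entries: list[PhenotypeEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypePanel":
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        entries = []
        for row in table.itertuples(index=False):
            entries.append(
                PhenotypeEntry(
                    substrate=row.substrate,
                    metabolite_id=getattr(row, "metabolite_id", "") or "unmapped",
                    ou=float(row.ou) if getattr(row, "ou", "") != "" else 0.0,
                    call=getattr(row, "call", ""),
                    model_call=getattr(row, "model_call", ""),
                )
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> Path:
        pd.DataFrame(
            [
                {
                    "substrate": e.substrate,
                    "metabolite_id": e.metabolite_id,
                    "ou": e.ou,
                    "call": e.call,
                    "model_call": e.model_call,
                    "reason": e.reason,
                }
                for e in self.entries
            ]
        ).to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def agreement(self) -> float:
        """Percent agreement, 100*(TP+TN)/N."""
        return 100.0 * (self.tp + self.tn) / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "n": self.n, "agreement": self.agreement}


def call_phenotypes(panel: PhenotypePanel, threshold: float = OU_THRESHOLD) -> PhenotypePanel:
    """Derive experimental calls from OU values: positive iff OU > threshold.

    Pre-existing "boundary" flags are preserved (scored negative downstream).
    """
    entries = []
    for e in panel.entries:
        if e.call == "boundary":
            entries.append(replace(e))
            continue
        entries.append(replace(e, call="positive" if e.ou > threshold else "negative"))
    return PhenotypePanel(entries)


def simulate_substrate_growth(
    model: MetabolicModel,
    metabolite_id: str,
    base_medium: Medium,
    uptake: float = TEST_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> tuple[str, str]:
    """(call, reason) for growth with one substrate opened on the base medium."""
    if metabolite_id in ("", "unmapped"):
        return "negative", "no exchange"
    work = model.copy()
    ex_id = "EX_" + metabolite_id
    if ex_id not in work.reactions:
        if metabolite_id not in work.metabolites:
            return "negative", "no exchange"
        try:
            add_boundary(work, metabolite_id, "exchange")
        except Exception:
            return "negative", "no exchange"
        return "negative", "no exchange"  # metabolite exists but the model declared no uptake route
    medium = Medium(
        uptake_limits={**base_medium.uptake_limits, ex_id: uptake},
        closed=set(base_medium.closed) - {ex_id},
    )
    if work.objective is None:
        return "negative", "no biomass objective"
    state = fba(work, work.objective[0], medium)
    if state.optimal and state.objective_value > growth_threshold:
        return "positive", ""
    return "negative", "no utilization route"


def tabulate(panel: PhenotypePanel) -> ConfusionTable:
    """Confusion table from experimental vs model calls already on the panel."""
    tp = tn = fp = fn = 0
    for e in panel.entries:
        exp = e.experimental_positive
        sim = e.model_call == "positive"
        if exp and sim:
            tp += 1
        elif exp and not sim:
            fn += 1
        elif sim:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp, tn, fp, fn)


def concordance(
    model: MetabolicModel,
    panel: PhenotypePanel,
    base_medium: Medium,
    uptake: float = TEST_UPTAKE,
) -> tuple[ConfusionTable, PhenotypePanel]:
    """Simulate every substrate and tabulate against the experimental calls."""
    entries = []
    for e in panel.entries:
        call, reason = simulate_substrate_growth(model, e.metabolite_id, base_medium, uptake)
        entries.append(replace(e, model_call=call, reason=reason))
    simulated = PhenotypePanel(entries)
    return tabulate(simulated), simulated


def extend_for_phenotypes(
    model: MetabolicModel,
    panel: PhenotypePanel,
    db: UniversalReactionDB,
    base_medium: Medium,
    uptake: float = TEST_UPTAKE,
) -> tuple[MetabolicModel, CurationReport]:
    """Resolve experimentally positive, model-negative substrates from the db.

    Substrates without an exchange get manually curated transport/exchange
    entries from the database's transport section; substrates with an
    exchange but no route are gap-filled against the biomass objective under
    that substrate.  Unfixable substrates stay listed as residual false
    negatives.  The report records before/after agreement.
    """
    before, simulated = concordance(model, panel, base_medium, uptake)
    report = CurationReport(stage="phenotype-extension")
    report.notes.append(f"agreement before: {before.agreement:.1f}% (n={before.n})")
    work = model.copy()
    for entry in simulated:
        if not (entry.experimental_positive and entry.model_call == "negative"):
            continue
        met = entry.metabolite_id
        ex_id = "EX_" + met
        if entry.reason == "no exchange":
            transport = [
                r for r in db.reactions.values()
                if r.subsystem.lower() == "transport" and met in r.stoichiometry
            ]
            if not transport:
                report.notes.append(f"residual false negative (no transport in db): {entry.substrate}")
                continue
            for rxn in transport:
                if rxn.id not in work.reactions:
                    work.add_reaction(rxn.copy())
                    report.added_reactions.append(rxn.id)
            for met_id in {m for r in transport for m in r.stoichiometry}:
                if work.metabolites[met_id].compartment == "e" and "EX_" + met_id not in work.reactions:
                    add_boundary(work, met_id, "exchange")
                    work.reactions["EX_" + met_id].lower_bound = 0.0
                    report.added_reactions.append("EX_" + met_id)
        if work.objective is None:
            continue
        # find the exchange feeding this substrate (possibly just added)
        ex_candidates = [x for x in (ex_id, "EX_" + met) if x in work.reactions]
        if not ex_candidates:
            ex_candidates = [
                "EX_" + m for m in work.metabolites
                if m.split("_")[0] == met.split("_")[0] and "EX_" + m in work.reactions
            ]
        if not ex_candidates:
            report.notes.append(f"residual false negative (unmapped): {entry.substrate}")
            continue
        medium = Medium(
            uptake_limits={**base_medium.uptake_limits, ex_candidates[0]: uptake},
            closed=set(base_medium.closed) - {ex_candidates[0]},
        )
        try:
            added, work = gapfill(work, db, work.objective[0], medium, threshold=GROWTH_THRESHOLD)
        except Exception:
            report.notes.append(f"residual false negative (unfixable): {entry.substrate}")
            continue
        report.added_reactions.extend(added)
    after, _ = concordance(work, panel, base_medium, uptake)
    report.notes.append(f"agreement after: {after.agreement:.1f}% (n={after.n})")
    return work, report
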