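"""Deterministic synthetic-fixture generators with known ground truth.

Every generator takes an explicit seed and uses one RNG algorithm
(numpy PCG64 via ``default_rng``), so the same spec always produces the
bit-identical fixture.  The generated objects emulate the situations the
curation pipeline must handle — a clean chemolithotroph-like toy network, a
seeded thermodynamically infeasible ATP-generating loop, seeded pathway gaps,
a phenotype panel with a thresholded OU signal, and a model split into two
overlapping annotation-style drafts — each with its ground truth returned
alongside, so tests never need an external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction, add_boundary
from .fba import Medium, fba
from .phenotype import OU_THRESHOLD, PhenotypeEntry, PhenotypePanel

#: OU bands well separated from the 114 threshold, so calls are unambiguous
#: unless label noise is explicitly requested.
OU_NEGATIVE_BAND = (20.0, 100.0)
OU_POSITIVE_BAND = (130.0, 300.0)


@dataclass(frozen=True)
class SyntheticSpec:
    n_metabolites: int = 10
    n_reactions: int = 14
    seed: int = 0
    gam: float = 10.0  # ATP per unit biomass in the toy biomass reaction
    uptake: float = 5.0  # substrate uptake bound written into the exchange


def generate_toy_model(spec: SyntheticSpec) -> MetabolicModel:
    """A stoichiometrically consistent, EGC-free toy model.

    Topology: one substrate exchange and transporter, an energy subsystem
    (substrate -> 2 ATP), a linear precursor chain, and a biomass reaction
    consuming the terminal precursor plus GAM ATP.  The analytic maximum
    growth is ``uptake / (1 + gam/2)``: each biomass unit costs one substrate
    for carbon and ``gam/2`` substrates for ATP.  Extra reactions beyond the
    chain are redundant parallel conversions, which leave the optimum
    unchanged.
    """
    if spec.n_metabolites < 3 or spec.n_reactions < spec.n_metabolites:
        raise ValueError("need n_reactions >= n_metabolites >= 3")
    rng = np.random.default_rng(spec.seed)
    m = MetabolicModel(f"toy_{spec.seed}")
    for met_id, comp in (("sub_e", "e"), ("sub_c", "c"), ("atp_c", "c"), ("adp_c", "c"),
                         ("pi_c", "c"), ("h_c", "c"), ("h2o_c", "c")):
        m.add_metabolite(Metabolite(met_id, compartment=comp))
    n_chain = max(1, spec.n_metabolites - 7)
    chain = [f"im{i}_c" for i in range(n_chain)]
    for met_id in chain:
        m.add_metabolite(Metabolite(met_id, compartment="c"))
    add_boundary(m, "sub_e", "exchange")
    m.reactions["EX_sub_e"].lower_bound = -spec.uptake
    m.add_reaction(Reaction("SUBt", {"sub_e": -1, "sub_c": 1}, lower_bound=0))
    m.add_reaction(
        Reaction("ENERGY", {"sub_c": -1, "adp_c": -2, "pi_c": -2, "atp_c": 2, "h2o_c": 2},
                 lower_bound=0, subsystem="Energy")
    )
    # free proton drain so ATP-hydrolysis-coupled reactions can run
    m.add_reaction(Reaction("HDRAIN", {"h_c": -1}, lower_bound=0))
    prev = "sub_c"
    for i, met_id in enumerate(chain):
        m.add_reaction(Reaction(f"CHAIN{i}", {prev: -1, met_id: 1}, lower_bound=0))
        prev = met_id
    m.add_reaction(
        Reaction(
            "BIOMASS",
            {prev: -1, "atp_c": -spec.gam, "h2o_c": -spec.gam,
             "adp_c": spec.gam, "pi_c": spec.gam},
            lower_bound=0, subsystem="Biomass",
        )
    )
    # pad with redundant parallel conversions drawn deterministically
    k = 0
    while len(m.reactions) < spec.n_reactions:
        i = int(rng.integers(0, len(chain)))
        src = chain[i]
        dst = chain[int(rng.integers(0, len(chain)))]
        if src == dst:
            dst = "sub_c"
        m.add_reaction(Reaction(f"PAR{k}", {src: -1, dst: 1}, lower_bound=0))
        k += 1
    m.set_objective("BIOMASS")
    m.validate()
    return m


def analytic_toy_growth(spec: SyntheticSpec) -> float:
    """Closed-form maximum growth of :func:`generate_toy_model`."""
    return spec.uptake / (1.0 + spec.gam / 2.0)


def seed_energy_cycle(
    model: MetabolicModel, cycle_size: int, seed: int = 0
) -> tuple[MetabolicModel, list[str]]:
    """Insert a reversible loop that nets ATP with all exchanges closed.

    The loop's ATP step is written in the thermodynamically sanctioned
    (ATP-consuming) direction but left reversible; run backwards around the
    loop it regenerates ATP from nothing — the classic energy-generating
    cycle.  Ground truth: the returned reaction ids are exactly the inserted
    loop, and a directionality reference marking the ATP step ``forward``
    repairs the model.
    """
    if cycle_size == 0:
        return model.copy(), []
    if cycle_size < 2:
        raise ValueError("cycle needs at least 2 reactions")
    out = model.copy()
    tag = f"egc{seed}"
    nodes = [f"{tag}_x{i}_c" for i in range(cycle_size)]
    for met_id in nodes:
        out.add_metabolite(Metabolite(met_id, compartment="c"))
    ids = []
    pump = f"{tag}_PUMP"
    out.add_reaction(
        Reaction(pump,
                 {nodes[0]: -1, "atp_c": -1, "h2o_c": -1,
                  nodes[1]: 1, "adp_c": 1, "pi_c": 1, "h_c": 1})
    )
    ids.append(pump)
    for i in range(1, cycle_size):
        rid = f"{tag}_LOOP{i}"
        out.add_reaction(
            Reaction(rid, {nodes[i]: -1, nodes[(i + 1) % cycle_size]: 1})
        )
        ids.append(rid)
    return out, ids


def seed_gaps(
    model: MetabolicModel,
    k: int,
    seed: int = 0,
    protect: set[str] = frozenset(),
    max_tries: int = 200,
) -> tuple[MetabolicModel, list[str]]:
    """Remove k reactions so that the biomass optimum becomes zero.

    Resamples until growth is actually broken; the removed ids are returned
    as ground truth for gap-fill recovery tests.
    """
    if k == 0:
        return model.copy(), []
    if model.objective is None:
        raise ValueError("model needs a biomass objective to break")
    candidates = sorted(
        set(model.reactions)
        - set(protect)
        - {model.objective[0]}
        - {r for r in model.reactions if model.is_exchange(r)}
    )
    if k >= len(candidates):
        raise ValueError("k too large for the model")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        removed = [candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)]
        out = model.copy()
        for rid in removed:
            out.remove_reaction(rid)
        out.objective = model.objective
        state = fba(out, out.objective[0])
        if (not state.optimal) or state.objective_value < 1e-9:
            return out, sorted(removed)
    raise RuntimeError(f"could not break growth with {k} removals in {max_tries} tries")


def generate_phenotype_panel(
    model: MetabolicModel,
    n_substrates: int,
    noise_rate: float = 0.0,
    seed: int = 0,
    base_medium: Medium | None = None,
) -> tuple[PhenotypePanel, dict[str, str]]:
    """Panel with OU signal drawn from the model's true growth behavior.

    Half of the substrates (deterministically interleaved) map to the model's
    real growth substrate and truly support growth; the rest map to dead-end
    metabolites added to the model in place, with an exchange but no
    utilization route.
    OU values are drawn above/below the 114 threshold according to the true
    call, then labels are flipped independently with probability
    ``noise_rate``.  Returns the panel and the ground-truth calls.
    """
    rng = np.random.default_rng(seed)
    work = model
    truth: dict[str, str] = {}
    entries: list[PhenotypeEntry] = []
    growth_met = next(
        (m for m in model.metabolites
         if model.metabolites[m].compartment == "e" and "EX_" + m in model.reactions),
        None,
    )
    if growth_met is None:
        raise ValueError("model has no exchangeable substrate")
    for i in range(n_substrates):
        name = f"substrate_{i}"
        if i % 2 == 0:
            met_id, true_call = growth_met, "positive"
        else:
            met_id = f"dead{i}_e"
            work.add_metabolite(Metabolite(met_id, compartment="e"))
            add_boundary(work, met_id, "exchange")
            work.reactions["EX_" + met_id].lower_bound = 0.0
            true_call = "negative"
        truth[name] = true_call
        observed = true_call
        if noise_rate > 0 and rng.random() < noise_rate:
            observed = "negative" if observed == "positive" else "positive"
        lo, hi = OU_POSITIVE_BAND if observed == "positive" else OU_NEGATIVE_BAND
        ou = float(rng.uniform(lo, hi))
        entries.append(PhenotypeEntry(name, met_id, ou=ou, call=observed))
    return PhenotypePanel(entries), truth


def split_for_merge(
    model: MetabolicModel, overlap_fraction: float, seed: int = 0
) -> tuple[MetabolicModel, MetabolicModel]:
    """Split a model into two overlapping drafts whose union is the model.

    A deterministic sample of ``overlap_fraction`` of the reactions is shared;
    the remainder is partitioned alternately.  Metabolites follow their
    reactions.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(model.reactions)
    n_shared = int(round(overlap_fraction * len(ids)))
    order = rng.permutation(len(ids))
    shared = {ids[i] for i in order[:n_shared]}
    rest = [ids[i] for i in order[n_shared:]]
    part_a = set(rest[0::2]) | shared
    part_b = set(rest[1::2]) | shared

    def _sub(name: str, keep: set[str]) -> MetabolicModel:
        sub = MetabolicModel(name, set(model.compartments))
        for rid in model.reactions:
            if rid not in keep:
                continue
            rxn = model.reactions[rid]
            for met_id in rxn.stoichiometry:
                sub.add_metabolite(model.metabolites[met_id].copy())
            sub.add_reaction(rxn.copy())
        if model.objective and model.objective[0] in sub.reactions:
            sub.objective = model.objective
        return sub

    return _sub(model.id + "_a", part_a), _sub(model.id + "_b", part_b)
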