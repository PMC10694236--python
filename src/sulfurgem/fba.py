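"""Linear-programming core: FBA, parsimonious FBA, flux ranges and yields.

Flux balance analysis solves

    max/min  c.v   s.t.  S.v = 0,  lb <= v <= ub

over the stoichiometric matrix S, with c an indicator (or sparse combination)
of objective reactions.  Parsimonious FBA (pFBA) fixes the objective at its
optimum and minimizes the total absolute flux sum, which selects the shortest
enzyme-usage route among alternate optima; it is realized here by splitting
every reaction into forward and reverse non-negative columns.

All solves go through scipy's HiGHS interface (dual simplex), which is
deterministic for a fixed model ordering.  Optimality/feasibility tolerances
are 1e-9; fluxes below 1e-6 are treated as zero when reporting active sets,
matching the 2-4 significant figures at which such predictions are usually
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import FluxState, MetabolicModel

FEASIBILITY_TOL = 1e-9
ZERO_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass(frozen=True)
class Objective:
    """A linear flux objective: a reaction id (or id -> coefficient map)."""

    coefficients: dict[str, float]
    sense: str = "maximize"

    @classmethod
    def of(cls, spec, sense: str = "maximize") -> "Objective":
        if isinstance(spec, Objective):
            return spec
        if isinstance(spec, str):
            return cls({spec: 1.0}, sense)
        return cls(dict(spec), sense)


@dataclass
class Medium:
    """Exchange-reaction uptake limits (mmol/gDW/h, non-negative).

    Applying a medium sets the lower bound of each listed exchange to
    ``-limit`` and of each closed exchange to 0 (secretion stays allowed).
    Exchanges not mentioned keep their model bounds.
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)
    closed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for ex, limit in self.uptake_limits.items():
            if limit < 0:
                raise ValueError(f"negative uptake limit for {ex}: {limit}")

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        """Return a bounds-adjusted copy of the model."""
        out = model.copy()
        for ex, limit in self.uptake_limits.items():
            if ex in out.reactions:
                out.reactions[ex].lower_bound = -limit
        for ex in self.closed:
            if ex in out.reactions:
                out.reactions[ex].lower_bound = max(0.0, out.reactions[ex].lower_bound)
        return out


def _solve(model: MetabolicModel, c: np.ndarray, *, extra_rows=None, extra_rhs=None):
    """min c.v s.t. S.v = 0 (+ optional extra equality rows), bounds."""
    S = model.stoichiometric_matrix()
    if extra_rows is not None:
        S = sparse.vstack([S, sparse.csr_matrix(np.atleast_2d(extra_rows))])
        rhs = np.concatenate([np.zeros(S.shape[0] - len(extra_rhs)), extra_rhs])
    else:
        rhs = np.zeros(S.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    res = linprog(
        c,
        A_eq=S,
        b_eq=rhs,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    return res


def _flux_state(model: MetabolicModel, res, objective_value: float | None = None) -> FluxState:
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxState({}, float("nan"), status)
    fluxes = {rid: float(v) for rid, v in zip(model.reactions, res.x)}
    return FluxState(fluxes, float(objective_value), "optimal")


def fba(
    model: MetabolicModel,
    objective=None,
    medium: Medium | None = None,
) -> FluxState:
    """Flux balance analysis; infeasibility is reported in status, never as 0."""
    if objective is None:
        if model.objective is None:
            raise ValueError("model has no objective and none was given")
        objective = Objective.of(model.objective[0], model.objective[1])
    objective = Objective.of(objective)
    work = medium.apply(model) if medium else model
    for rid in objective.coefficients:
        if rid not in work.reactions:
            raise KeyError(f"objective reaction {rid} not in model")
    sign = -1.0 if objective.sense == "maximize" else 1.0
    c = np.zeros(len(work.reactions))
    index = {rid: i for i, rid in enumerate(work.reactions)}
    for rid, coef in objective.coefficients.items():
        c[index[rid]] = sign * coef
    res = _solve(work, c)
    return _flux_state(work, res, sign * res.fun if res.status == 0 else None)


def pfba(
    model: MetabolicModel,
    objective=None,
    medium: Medium | None = None,
    optimum_fraction: float = 1.0,
) -> FluxState:
    """Parsimonious FBA.

    The objective flux is fixed at ``optimum_fraction`` times the FBA optimum
    and the total absolute flux sum is minimized.  The returned
    ``objective_value`` is the minimized flux sum; the fluxes are the
    parsimonious vector.
    """
    if objective is None and model.objective is not None:
        objective = Objective.of(model.objective[0], model.objective[1])
    objective = Objective.of(objective)
    first = fba(model, objective, medium)
    if not first.optimal:
        return first
    work = medium.apply(model) if medium else model.copy()
    # fix the objective combination at its (scaled) optimum via an extra row
    index = {rid: i for i, rid in enumerate(work.reactions)}
    n = len(work.reactions)
    row = np.zeros(n)
    for rid, coef in objective.coefficients.items():
        row[index[rid]] = coef
    target = optimum_fraction * first.objective_value
    # split: v = v+ - v-, minimize sum(v+ + v-)
    S = work.stoichiometric_matrix()
    A = sparse.vstack([S, sparse.csr_matrix(row)])
    A = sparse.hstack([A, -A]).tocsr()
    rhs = np.concatenate([np.zeros(S.shape[0]), [target]])
    lb = np.array([r.lower_bound for r in work.reactions.values()])
    ub = np.array([r.upper_bound for r in work.reactions.values()])
    bounds = [(max(0.0, l), max(0.0, u)) for l, u in zip(lb, ub)] + [
        (max(0.0, -u), max(0.0, -l)) for l, u in zip(lb, ub)
    ]
    res = linprog(
        np.ones(2 * n),
        A_eq=A,
        b_eq=rhs,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxState({}, float("nan"), status)
    net = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v) for rid, v in zip(work.reactions, net)}
    return FluxState(fluxes, float(res.fun), "optimal")


def flux_range(
    model: MetabolicModel,
    reaction: str,
    medium: Medium | None = None,
    objective=None,
    optimum_fraction: float = 1.0,
) -> tuple[float, float]:
    """Min and max flux of one reaction with the objective fixed at optimum."""
    work = medium.apply(model) if medium else model.copy()
    extra_rows, extra_rhs = None, None
    if objective is not None:
        obj = Objective.of(objective)
    elif model.objective is not None:
        obj = Objective.of(model.objective[0], model.objective[1])
    else:
        obj = None
    if obj is not None:
        first = fba(model, obj, medium)
        if not first.optimal:
            raise ValueError(f"FBA not optimal ({first.status}); cannot fix objective")
        index = {rid: i for i, rid in enumerate(work.reactions)}
        row = np.zeros(len(work.reactions))
        for rid, coef in obj.coefficients.items():
            row[index[rid]] = coef
        extra_rows = row
        extra_rhs = [optimum_fraction * first.objective_value]
    c = np.zeros(len(work.reactions))
    c[list(work.reactions).index(reaction)] = 1.0
    lo = _solve(work, c, extra_rows=extra_rows, extra_rhs=extra_rhs)
    hi = _solve(work, -c, extra_rows=extra_rows, extra_rhs=extra_rhs)
    if lo.status != 0 or hi.status != 0:
        raise ValueError(f"flux_range LP not optimal for {reaction}")
    return float(lo.fun), float(-hi.fun)


def ensure_demand(model: MetabolicModel, met_id: str) -> str:
    """Demand reaction id for a metabolite, adding it if absent (in place)."""
    from .core import add_boundary

    rxn_id = "DM_" + met_id
    if rxn_id not in model.reactions:
        add_boundary(model, met_id, "demand")
    return rxn_id


def atp_demand_id(model: MetabolicModel) -> str:
    """The ATP-dissipation reaction used as the 'ATP production rate' proxy.

    A hydrolysis reaction (ATP + H2O -> ADP + Pi + H) is preferred when the
    cofactor metabolites exist; otherwise a plain demand on ATP is used.
    """
    for rid in ("ATPM", "DM_atp_c"):
        if rid in model.reactions:
            return rid
    needed = {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}
    if all(m in model.metabolites for m in needed):
        from .core import Reaction

        model.add_reaction(
            Reaction("ATPM", dict(needed), name="ATP maintenance/dissipation",
                     lower_bound=0.0, upper_bound=1000.0, subsystem="Maintenance")
        )
        return "ATPM"
    if "atp_c" in model.metabolites:
        return ensure_demand(model, "atp_c")
    raise KeyError("model has no recognizable cytoplasmic ATP metabolite")


def max_yield(
    model: MetabolicModel,
    product_met: str,
    substrate_exchange: str,
    rate: float,
    closed: set[str] = frozenset(),
) -> float:
    """Maximum production rate of a metabolite at a fixed substrate uptake.

    The substrate exchange lower bound is set to ``-rate``; exchanges listed
    in ``closed`` (competing energy sources) are blocked for uptake.  By LP
    homogeneity the yield scales linearly in ``rate``.

    For ATP the sink is the hydrolysis reaction (ATP + H2O -> ADP + Pi + H),
    not a plain demand: draining ATP without returning ADP would starve the
    adenylate pool and force a zero yield.
    """
    work = model.copy()
    demand = atp_demand_id(work) if product_met == "atp_c" else ensure_demand(work, product_met)
    medium = Medium(uptake_limits={substrate_exchange: rate}, closed=set(closed))
    state = fba(work, demand, medium)
    if not state.optimal:
        raise ValueError(f"yield LP {state.status}")
    return state.objective_value
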