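"""Independent brute-force LP oracle for tiny flux networks.

Enumerates the vertices of the flux polytope {S.v = 0, l <= v <= u} by
fixing every choice of n - rank(S) variables at one of their bounds and
solving the remaining square system, keeping feasible solutions.  Because a
bounded LP attains its optimum at a vertex, the best vertex objective equals
the FBA optimum; the oracle shares no code with the solver under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(model, tol: float = 1e-9) -> list[dict[str, float]]:
    ids = list(model.reactions)
    S = model.stoichiometric_matrix(dense=True)
    lb = np.array([model.reactions[r].lower_bound for r in ids])
    ub = np.array([model.reactions[r].upper_bound for r in ids])
    n = len(ids)
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    vertices: list[dict[str, float]] = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            A = S[:, free]
            sol, residuals, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            vertices.append(dict(zip(ids, v)))
    return vertices


def brute_force_optimum(model, objective_id: str, sense: str = "maximize") -> float:
    """Best vertex value of one reaction's flux; oracle for the FBA optimum."""
    values = [v[objective_id] for v in enumerate_vertices(model)]
    if not values:
        raise ValueError("no feasible vertex found")
    return max(values) if sense == "maximize" else min(values)


def min_flux_sum_at_optimum(model, objective_id: str, tol: float = 1e-6) -> float:
    """Smallest total |flux| among optimal vertices; oracle for pFBA.

    The pFBA optimum is attained at a vertex of the restricted polytope whose
    vertices are a subset of vertices of the original polytope union new ones
    from the added equality; for the small networks used in tests the
    optimal-face vertices are all original vertices, which we filter here.
    """
    vertices = enumerate_vertices(model)
    best = max(v[objective_id] for v in vertices)
    optimal = [v for v in vertices if v[objective_id] >= best - tol]
    return min(sum(abs(x) for x in v.values()) for v in optimal)
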