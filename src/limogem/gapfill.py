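"""Gap-filling: minimal reaction additions that restore biomass feasibility.

Given a base model that cannot reach a growth floor and a universal pool of
candidate reactions (an ordinary model whose flux-bound magnitudes are
ignored — only directionality is kept), find an irreducible set of pool
reactions whose addition lifts the biomass objective above the floor.

Two modes:

* the default heuristic relaxes all pool reactions into the network,
  minimizes the total absolute pool flux by LP subject to growth >= floor,
  takes the support, and prunes it to irreducibility;
* exhaustive mode enumerates candidate subsets by increasing cardinality
  (lexicographic within a cardinality) and is provably minimum-cardinality;
  it is the default for pools of at most 15 candidates.

Both are deterministic; ties among equal-cardinality solutions break
lexicographically on reaction ids.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .errors import SolverError, UnfillableError
from .model import Model, Reaction, reaction_signature
from .reconstruct import _merge_metabolite
from .simulate import fba

logger = logging.getLogger(__name__)

__all__ = ["GapfillProblem", "GapfillSolution", "find_gapfill_set", "apply_gapfill"]

#: Pools up to this size use exhaustive (provably minimal) search by default.
EXHAUSTIVE_LIMIT = 15

_FEAS_TOL = 1e-9
_SUPPORT_TOL = 1e-9


@dataclass
class GapfillProblem:
    """A gap-filling instance."""

    base: Model
    pool: Model
    objective_id: Optional[str] = None
    min_growth: float = 1e-6

    def __post_init__(self) -> None:
        if self.min_growth <= 0:
            raise ValueError("min_growth must be positive")
        if self.objective_id is None:
            self.objective_id = self.base.biomass_reaction_id
        if self.objective_id is None:
            raise ValueError("no objective reaction for gap-filling")


@dataclass
class GapfillSolution:
    """An irreducible (or provably minimal) enabling set."""

    added_reaction_ids: list[str]
    achieved_growth: float
    proven_minimal: bool
    pool_id: str = ""


def _candidate_reactions(problem: GapfillProblem) -> list[Reaction]:
    """Pool reactions absent from the base (by stoichiometric signature),
    with bound magnitudes opened; only directionality is preserved."""
    base_sigs = {reaction_signature(r) for r in problem.base.reactions}
    candidates = []
    for rxn in problem.pool.reactions:
        if reaction_signature(rxn) in base_sigs:
            continue
        cand = rxn.copy()
        cand.lower_bound = -1000.0 if rxn.lower_bound < 0 else 0.0
        cand.upper_bound = 1000.0 if rxn.upper_bound > 0 else 0.0
        if problem.base.has_reaction(cand.id):
            cand.id = f"{cand.id}__pool"
        candidates.append(cand)
    candidates.sort(key=lambda r: r.id)
    return candidates


def _merged(problem: GapfillProblem, candidates: list[Reaction]) -> Model:
    merged = problem.base.copy()
    for cand in candidates:
        for met_id in cand.stoichiometry:
            _merge_metabolite(merged, problem.pool.metabolite(met_id))
        merged.add_reaction(cand.copy())
    return merged


def _growth(merged: Model, problem: GapfillProblem, active: set[str], all_ids: list[str]) -> float:
    extra = {rid: (0.0, 0.0) for rid in all_ids if rid not in active}
    sol = fba(merged, problem.objective_id, extra_constraints=extra or None)
    if sol.status != "optimal":
        return -math.inf
    return sol.objective_value


def _blocked_precursors(merged: Model, problem: GapfillProblem) -> list[str]:
    """Biomass substrates that cannot be produced even with the full pool."""
    biomass = merged.reaction(problem.objective_id)
    blocked = []
    for met_id, coeff in sorted(biomass.stoichiometry.items()):
        if coeff >= 0:
            continue
        probe = merged.copy()
        probe.add_reaction(
            Reaction(f"DM_probe_{met_id}", stoichiometry={met_id: -1.0}, lower_bound=0.0, upper_bound=1000.0)
        )
        sol = fba(probe, f"DM_probe_{met_id}")
        if sol.status != "optimal" or sol.objective_value <= _FEAS_TOL:
            blocked.append(met_id)
    return blocked


def _lp_support(merged: Model, problem: GapfillProblem, cand_ids: list[str]) -> list[str]:
    """Minimize total |flux| through pool reactions subject to growth >= floor."""
    rxn_ids = merged.reaction_ids
    pos = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    k = len(cand_ids)
    lb = np.array([r.lower_bound for r in merged.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in merged.reactions], dtype=float)
    j_obj = pos[problem.objective_id]
    lb[j_obj] = max(lb[j_obj], problem.min_growth)

    S = merged.stoichiometric_matrix()
    m = S.shape[0]
    # variables: v (n) then t (k) with t_i >= |v_cand_i|
    A_eq = np.hstack([S, np.zeros((m, k))])
    b_eq = np.zeros(m)
    A_ub = np.zeros((2 * k, n + k))
    for i, rid in enumerate(cand_ids):
        j = pos[rid]
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + i] = -1.0
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + i] = -1.0
    c = np.zeros(n + k)
    c[n:] = 1.0
    bounds = [(lb[j], ub[j]) for j in range(n)] + [(0.0, None)] * k
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * k), A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return []  # infeasible even with everything open: caller handles
    if res.status != 0:
        raise SolverError(f"gap-fill relaxation LP failed: {res.message}")
    return [rid for i, rid in enumerate(cand_ids) if abs(res.x[pos[rid]]) > _SUPPORT_TOL]


def find_gapfill_set(problem: GapfillProblem, exhaustive: Optional[bool] = None) -> GapfillSolution:
    """Find an irreducible enabling reaction set for the growth floor.

    ``exhaustive=None`` (default) chooses exhaustive search when the
    candidate pool has at most 15 members, the LP-rounding heuristic
    otherwise.  Raises :class:`UnfillableError`, naming blocked biomass
    precursors, when even the full pool cannot reach the floor.
    """
    candidates = _candidate_reactions(problem)
    cand_ids = [c.id for c in candidates]
    merged = _merged(problem, candidates)
    floor = problem.min_growth - _FEAS_TOL
    pool_id = problem.pool.id

    base_growth = _growth(merged, problem, set(), cand_ids)
    if base_growth >= floor:
        return GapfillSolution([], base_growth, proven_minimal=True, pool_id=pool_id)

    full_growth = _growth(merged, problem, set(cand_ids), cand_ids)
    if full_growth < floor:
        blocked = _blocked_precursors(merged, problem)
        raise UnfillableError(
            f"model {problem.base.id!r} cannot reach growth {problem.min_growth} even with the "
            f"full pool {pool_id!r}; blocked biomass precursors: {blocked}",
            blocked_precursors=blocked,
        )

    if exhaustive is None:
        exhaustive = len(cand_ids) <= EXHAUSTIVE_LIMIT

    if exhaustive:
        for size in range(1, len(cand_ids) + 1):
            for combo in itertools.combinations(cand_ids, size):
                growth = _growth(merged, problem, set(combo), cand_ids)
                if growth >= floor:
                    return GapfillSolution(list(combo), growth, proven_minimal=True, pool_id=pool_id)
        raise UnfillableError("exhaustive search found no enabling subset")  # pragma: no cover

    support = _lp_support(merged, problem, cand_ids)
    if not support:
        support = list(cand_ids)
    # prune to irreducibility, lexicographic removal order for determinism
    kept = sorted(support)
    for rid in sorted(support):
        trial = [r for r in kept if r != rid]
        if _growth(merged, problem, set(trial), cand_ids) >= floor:
            kept = trial
    growth = _growth(merged, problem, set(kept), cand_ids)
    return GapfillSolution(sorted(kept), growth, proven_minimal=False, pool_id=pool_id)


def apply_gapfill(model: Model, solution: GapfillSolution, pool: Model) -> Model:
    """Merge a gap-fill solution into a model.

    Added reactions carry provenance ``gapfill:<pool-id>`` and an empty GPR
    (no gene evidence).  Id collisions are resolved by a provenance suffix
    and logged.
    """
    out = model.copy()
    pool_by_id = {r.id: r for r in pool.reactions}
    pool_by_id.update({f"{r.id}__pool": r for r in pool.reactions})
    for rid in solution.added_reaction_ids:
        src = pool_by_id.get(rid)
        if src is None:
            raise ValueError(f"solution reaction {rid!r} is not in pool {pool.id!r}")
        rxn = src.copy()
        # same bound opening as the search: directionality only
        rxn.lower_bound = -1000.0 if src.lower_bound < 0 else 0.0
        rxn.upper_bound = 1000.0 if src.upper_bound > 0 else 0.0
        rxn.gpr = None
        rxn.annotations["provenance"] = f"gapfill:{pool.id}"
        for met_id in rxn.stoichiometry:
            _merge_metabolite(out, pool.metabolite(met_id))
        if out.has_reaction(rxn.id):
            new_id = f"{rxn.id}__gapfill_{pool.id}"
            logger.info("gap-fill id collision: %r renamed to %r", rxn.id, new_id)
            rxn.id = new_id
        out.add_reaction(rxn)
    return out
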