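"""Flux balance analysis and phenotype-screen protocols.

FBA maximizes a reaction flux subject to steady state (S·v = 0) and flux
bounds, solved as a linear program through SciPy's HiGHS backend.  On top
of the solver sit the four screening protocols used to characterize
lactic-acid-bacterium models:

* growth on a medium (biomass objective);
* growth with the Embden–Meyerhof–Parnas branch capped at phosphofructokinase
  and fructose-1,6-bisphosphate aldolase, forcing flux through the
  phosphoketolase branch;
* single-nutrient omission screens (amino-acid auxotrophy prediction);
* product-synthesis capability (maximize a secretion flux; any positive
  rate counts as capability).

Growth rates below 1e-10 1/h, or infeasible problems, count as no growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import linprog

from .errors import MediumError, SolverError, ValidationError
from .model import Model, Reaction, classify_reaction

__all__ = [
    "GROWTH_THRESHOLD",
    "FluxDistribution",
    "GrowthVerdict",
    "PathwayCap",
    "fba",
    "apply_medium",
    "growth_with_cap",
    "omit_nutrient_screen",
    "production_capability",
]

#: Growth-rate floor (1/h) below which a model counts as non-growing.
GROWTH_THRESHOLD = 1e-10

#: Secretion flux above this counts as synthesis capability.
CAPABILITY_TOLERANCE = 1e-9


@dataclass
class FluxDistribution:
    """An FBA solution: solver status, objective value and per-reaction flux."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class GrowthVerdict:
    """Growth rate (1/h) with the no-growth rule already applied."""

    rate: float
    grows: bool

    @classmethod
    def from_solution(cls, sol: FluxDistribution) -> "GrowthVerdict":
        grows = sol.status == "optimal" and sol.objective_value >= GROWTH_THRESHOLD
        rate = sol.objective_value if sol.status == "optimal" else 0.0
        return cls(rate=rate, grows=grows)


@dataclass
class PathwayCap:
    """An upper flux cap applied to a set of reactions (e.g. PFK and the
    fructose-1,6-bisphosphate aldolase step, to throttle the EMP branch)."""

    reaction_ids: tuple[str, ...]
    max_flux: float

    def __post_init__(self) -> None:
        if self.max_flux < 0:
            raise ValueError("cap flux must be non-negative")
        self.reaction_ids = tuple(self.reaction_ids)


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def fba(
    model: Model,
    objective_id: Optional[str] = None,
    extra_constraints: Optional[dict[str, tuple[float, float]]] = None,
) -> FluxDistribution:
    """Maximize ``objective_id`` flux subject to S·v = 0 and bounds.

    ``extra_constraints`` maps reaction id -> (lb, ub) overrides applied for
    this solve only; the model is never mutated.  Unboundedness and
    infeasibility are reported in the status, not raised.
    """
    objective_id = objective_id or model.objective_reaction_id
    if objective_id is None:
        raise ValidationError("no objective reaction specified")
    model.reaction(objective_id)  # raises IntegrityError if absent

    rxn_ids = model.reaction_ids
    pos = {r: j for j, r in enumerate(rxn_ids)}
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if extra_constraints:
        for rid, (lo, hi) in extra_constraints.items():
            j = pos.get(rid)
            if j is None:
                raise ValidationError(f"constraint on unknown reaction {rid!r}")
            lb[j], ub[j] = lo, hi
    bad = np.nonzero(lb > ub)[0]
    if bad.size:
        raise ValidationError(
            f"reaction {rxn_ids[bad[0]]!r}: lower bound {lb[bad[0]]} > upper bound {ub[bad[0]]}"
        )

    S = model.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    c[pos[objective_id]] = -1.0  # linprog minimizes

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed on model {model.id!r}: {res.message}")
    if status != "optimal":
        return FluxDistribution(status=status, objective_value=math.nan)
    fluxes = {rid: float(res.x[j]) for rid, j in pos.items()}
    return FluxDistribution(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def apply_medium(model: Model, medium: "MediumSpec | dict[str, float]") -> Model:
    """Return a copy of the model constrained to the given growth medium.

    Exchange lower bounds of medium members become -(max uptake); every
    other exchange lower bound becomes 0 (secretion-only).  Upper bounds are
    untouched.  Applying a second medium fully overrides the first.
    """
    rates = medium.uptake_rates if hasattr(medium, "uptake_rates") else dict(medium)
    out = model.copy()
    seen: set[str] = set()
    for rxn in out.reactions:
        if classify_reaction(rxn, out) != "exchange":
            continue
        (met_id,) = rxn.stoichiometry
        if met_id in rates:
            rxn.lower_bound = -abs(rates[met_id])
            seen.add(met_id)
        else:
            rxn.lower_bound = 0.0
    missing = set(rates) - seen
    if missing:
        raise MediumError(
            f"medium metabolites without exchange reactions in model {model.id!r}: "
            f"{sorted(missing)}"
        )
    return out


def growth_with_cap(
    model: Model,
    medium: "MediumSpec | dict[str, float] | None" = None,
    cap: Optional[PathwayCap] = None,
) -> GrowthVerdict:
    """Biomass FBA with optional medium and pathway flux caps.

    Capped reactions get upper bound min(existing, cap.max_flux).
    """
    m = apply_medium(model, medium) if medium is not None else model
    extra: dict[str, tuple[float, float]] = {}
    if cap is not None:
        for rid in cap.reaction_ids:
            rxn = m.reaction(rid)
            extra[rid] = (rxn.lower_bound, min(rxn.upper_bound, cap.max_flux))
    sol = fba(m, m.biomass_reaction_id, extra_constraints=extra or None)
    return GrowthVerdict.from_solution(sol)


def omit_nutrient_screen(
    model: Model,
    medium: "MediumSpec | dict[str, float]",
    nutrients: Iterable[str],
) -> dict[str, GrowthVerdict]:
    """Single-nutrient omission screen.

    For each nutrient independently, its uptake is shut off (exchange lower
    bound 0) and biomass FBA is run; the model passed in is left untouched.
    Omitting a nutrient absent from the medium reproduces the baseline.
    """
    constrained = apply_medium(model, medium)
    verdicts: dict[str, GrowthVerdict] = {}
    for nutrient in nutrients:
        ex = constrained.exchange_for(nutrient)
        extra = {ex.id: (0.0, ex.upper_bound)} if ex is not None else None
        sol = fba(constrained, constrained.biomass_reaction_id, extra_constraints=extra)
        verdicts[nutrient] = GrowthVerdict.from_solution(sol)
    return verdicts


def production_capability(
    model: Model,
    product_id: str,
    medium: "MediumSpec | dict[str, float] | None" = None,
    require_growth: Optional[float] = None,
) -> tuple[bool, float]:
    """Can the model secrete ``product_id``?  Returns (capability, max rate).

    The secretion (exchange) flux of the product is maximized; capability is
    a positive maximum.  If the extracellular metabolite has no exchange
    reaction yet, a secretion-only one is added on the fly.  Growth is not
    required unless ``require_growth`` sets a floor.
    """
    m = apply_medium(model, medium) if medium is not None else model.copy()
    met_id = product_id if m.has_metabolite(product_id) else product_id + "_e"
    met = m.metabolite(met_id)  # raises IntegrityError if unknown
    if met.compartment != "e":
        raise ValidationError(f"product {met_id!r} is not extracellular")
    ex = m.exchange_for(met_id)
    if ex is None:
        ex = Reaction(f"EX_{met_id}", stoichiometry={met_id: -1.0}, lower_bound=0.0, upper_bound=1000.0)
        m.add_reaction(ex)
    extra = None
    if require_growth is not None and m.biomass_reaction_id is not None:
        bio = m.reaction(m.biomass_reaction_id)
        extra = {bio.id: (require_growth, bio.upper_bound)}
    sol = fba(m, ex.id, extra_constraints=extra)
    if sol.status != "optimal":
        return False, 0.0
    return sol.objective_value > CAPABILITY_TOLERANCE, sol.objective_value
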