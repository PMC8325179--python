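"""Constraint-based model data structures and model-quality statistics.

A :class:`Model` is a stoichiometric reconstruction: metabolites split over
a cytosol (``c``) and an extracellular (``e``) compartment, reactions with
flux bounds in mmol/gDW/h and boolean gene associations, and a biomass
pseudo-reaction whose flux represents growth rate (1/h).

Reactions fall into three kinds, matching the usual model-characteristics
tables:

* ``exchange`` — boundary pseudo-reaction touching exactly one extracellular
  metabolite (negative flux = uptake, positive = secretion);
* ``transport`` — touches both compartments;
* ``internal`` — confined to a single compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .errors import IntegrityError, ValidationError
from .gpr import GPR

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "Model",
    "ModelStats",
    "BalanceReport",
    "classify_reaction",
    "model_stats",
    "check_balances",
    "reaction_signature",
    "parse_formula",
]

#: Compartment suffix -> descriptive name. Only cytosol and extracellular
#: compartments are supported; other suffixes are rejected at validation.
COMPARTMENTS = {"c": "cytosol", "e": "extracellular"}


def parse_formula(text: str) -> dict[str, int]:
    """Parse a chemical formula like ``C6H12O6`` into an element->count map."""
    import re

    if not text:
        return {}
    counts: dict[str, int] = {}
    for element, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


def formula_to_string(formula: dict[str, int]) -> str:
    parts = []
    for element in sorted(formula):
        n = formula[element]
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


@dataclass
class Metabolite:
    """A compartment-suffixed metabolite, e.g. ``glc_c`` / ``glc_e``."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[dict[str, int]] = None
    charge: Optional[int] = None
    annotations: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "Metabolite":
        return replace(
            self,
            formula=dict(self.formula) if self.formula is not None else None,
            annotations=dict(self.annotations),
        )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a gene association.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  Bounds are in mmol/gDW/h; ``gpr`` is ``None`` when the
    reaction has no gene association.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: Optional[GPR] = None
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            annotations=dict(self.annotations),
        )


@dataclass
class Model:
    """A genome-scale metabolic model."""

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    biomass_reaction_id: Optional[str] = None
    objective_reaction_id: Optional[str] = None

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- access -------------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise IntegrityError(f"unknown metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise IntegrityError(f"unknown reaction {rxn_id!r} in model {self.id!r}")

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    # -- mutation -----------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn
        self.genes |= rxn.genes()

    def remove_reaction(self, rxn_id: str) -> None:
        rxn = self.reaction(rxn_id)
        self.reactions.remove(rxn)
        del self._rxn_index[rxn_id]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if classify_reaction(r, self) == "exchange"]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        """The exchange reaction whose single metabolite is ``met_id``."""
        for r in self.reactions:
            if list(r.stoichiometry) == [met_id] and classify_reaction(r, self) == "exchange":
                return r
        return None

    def copy(self, new_id: Optional[str] = None) -> "Model":
        return Model(
            id=new_id or self.id,
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            objective_reaction_id=self.objective_reaction_id,
        )

    # -- matrix -------------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, one row per metabolite, one column per reaction."""
        met_pos = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Raise on any violated structural invariant."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if m.compartment not in COMPARTMENTS:
                raise ValidationError(
                    f"metabolite {m.id!r} in unsupported compartment {m.compartment!r}; "
                    f"supported: {sorted(COMPARTMENTS)}"
                )
            if m.formula is not None and any(
                (not isinstance(v, int)) or v < 0 for v in m.formula.values()
            ):
                raise ValidationError(f"metabolite {m.id!r} has negative/non-integer formula counts")
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise IntegrityError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
            for g in r.genes():
                if g not in self.genes:
                    raise IntegrityError(f"reaction {r.id!r} GPR references undeclared gene {g!r}")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self._rxn_index:
            raise IntegrityError(f"biomass reaction {self.biomass_reaction_id!r} not in model")
        if (
            self.objective_reaction_id is not None
            and self.objective_reaction_id not in self._rxn_index
        ):
            raise IntegrityError(f"objective reaction {self.objective_reaction_id!r} not in model")


# ---------------------------------------------------------------------------
# classification & statistics


def classify_reaction(rxn: Reaction, model: Model) -> str:
    """Classify a reaction as ``exchange``, ``transport`` or ``internal``.

    Exchange: a single metabolite, and it is extracellular.  Transport:
    metabolites in at least two compartments.  Internal: one compartment.
    """
    if not rxn.stoichiometry:
        raise ValidationError(f"reaction {rxn.id!r} has no metabolites")
    comps = {model.metabolite(m).compartment for m in rxn.stoichiometry}
    if len(rxn.stoichiometry) == 1 and comps == {"e"}:
        return "exchange"
    if len(comps) >= 2:
        return "transport"
    return "internal"


@dataclass
class ModelStats:
    """Counts per model-characteristics category."""

    n_genes: int
    n_reactions: int
    n_internal: int
    n_transport: int
    n_exchange: int
    n_metabolites: int
    n_with_gpr: int
    gpr_fraction: float

    def to_rows(self) -> list[tuple[str, object]]:
        """Rows in model-characteristics table order."""
        return [
            ("Genes", self.n_genes),
            ("Reactions", self.n_reactions),
            ("With GPR", f"{self.n_with_gpr} ({self.gpr_fraction:.0%})"),
            ("Internal", self.n_internal),
            ("Transport", self.n_transport),
            ("Exchange", self.n_exchange),
            ("Metabolites", self.n_metabolites),
        ]


def model_stats(model: Model) -> ModelStats:
    """Category counts and the fraction of reactions carrying a GPR."""
    kinds = {"internal": 0, "transport": 0, "exchange": 0}
    n_gpr = 0
    for r in model.reactions:
        kinds[classify_reaction(r, model)] += 1
        if r.gpr is not None:
            n_gpr += 1
    n_rxn = len(model.reactions)
    return ModelStats(
        n_genes=len(model.genes),
        n_reactions=n_rxn,
        n_internal=kinds["internal"],
        n_transport=kinds["transport"],
        n_exchange=kinds["exchange"],
        n_metabolites=len(model.metabolites),
        n_with_gpr=n_gpr,
        gpr_fraction=(n_gpr / n_rxn) if n_rxn else 0.0,
    )


# ---------------------------------------------------------------------------
# mass / charge balance


@dataclass
class BalanceReport:
    """Outcome of a mass/charge balance check.

    ``imbalances`` holds ``(reaction_id, {element_or_'charge': net})`` for
    every checkable non-exchange reaction with a nonzero net; ``uncovered``
    lists reactions skipped because a participating metabolite lacks a
    formula or charge (missing data, not imbalance).
    """

    imbalances: list[tuple[str, dict[str, float]]]
    uncovered: list[str]


def check_balances(model: Model, tol: float = 1e-9) -> BalanceReport:
    """Report element and charge imbalances for non-exchange reactions.

    Exchange reactions are boundary pseudo-reactions and are excluded by
    convention.  Reactions involving a metabolite without formula or charge
    are reported in the coverage section instead of as imbalances.
    """
    imbalances: list[tuple[str, dict[str, float]]] = []
    uncovered: list[str] = []
    for r in model.reactions:
        if classify_reaction(r, model) == "exchange":
            continue
        mets = [model.metabolite(m) for m in r.stoichiometry]
        if any(m.formula is None or m.charge is None for m in mets):
            uncovered.append(r.id)
            continue
        net: dict[str, float] = {}
        for met_id, coeff in r.stoichiometry.items():
            met = model.metabolite(met_id)
            for element, n in met.formula.items():
                net[element] = net.get(element, 0.0) + coeff * n
            net["charge"] = net.get("charge", 0.0) + coeff * met.charge
        nonzero = {k: v for k, v in net.items() if abs(v) > tol}
        if nonzero:
            imbalances.append((r.id, nonzero))
    return BalanceReport(imbalances=imbalances, uncovered=uncovered)


# ---------------------------------------------------------------------------
# canonical reaction identity


def reaction_signature(rxn: Reaction, precision: int = 9) -> tuple:
    """Direction-normalized stoichiometric signature of a reaction.

    Two reactions with the same participating metabolites and coefficients
    share a signature regardless of id, name or GPR.  A reversible reaction
    and its reversed writing normalize to the same signature; an
    irreversible reaction written backwards (only negative flux allowed) is
    flipped to its forward sense first.  Irreversible and reversible
    versions of the same stoichiometry are distinct.
    """
    items = tuple(
        sorted((m, round(c, precision)) for m, c in rxn.stoichiometry.items() if c != 0)
    )
    flipped = tuple(sorted((m, -c) for m, c in items))
    if rxn.lower_bound < 0 and rxn.upper_bound > 0:
        return ("rev", min(items, flipped))
    if rxn.upper_bound <= 0:  # written backwards; forward sense is the flip
        return ("irr", flipped)
    return ("irr", items)
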