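"""Core/pan model construction and cross-group element classification.

Across a panel of strain models grouped by host (herbivore, omnivore,
sourdough, ...), the core model is the intersection of reactions and the
pan model their union.  Elements (genes, reactions or metabolites) are then
classified over the union of the per-group pan sets:

* ``common`` — present in every group's pan set;
* ``specific`` — present in exactly one group's pan set;
* ``dispensable`` — present in more than one but not all groups.

Reactions are compared by a direction-normalized stoichiometric signature
by default, which is robust across pipelines; an id-based mode exists for
panels built in one shared namespace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .errors import ReconciliationError, ValidationError
from .model import Metabolite, Model, Reaction, classify_reaction, reaction_signature

__all__ = [
    "StrainPanel",
    "ElementClassification",
    "GroupSummary",
    "element_key",
    "core_model",
    "pan_model",
    "classify_elements",
    "group_summary",
]

ElementKind = Literal["gene", "reaction", "metabolite"]
IdentityMode = Literal["signature", "id"]


@dataclass
class StrainPanel:
    """Strain models with host-group labels."""

    members: list[tuple[str, Model, str]]  # (strain id, model, group label)

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.members]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate strain ids in panel")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, _, g in self.members:
            if g not in seen:
                seen.append(g)
        return seen

    def models_in(self, group: str) -> list[Model]:
        return [m for _, m, g in self.members if g == group]

    @property
    def models(self) -> list[Model]:
        return [m for _, m, _ in self.members]


def element_key(element, kind: ElementKind, identity: IdentityMode = "signature"):
    """Canonical identity of a model element for cross-model comparison.

    Genes and metabolites are keyed by id.  Reactions use the
    direction-normalized stoichiometric signature (GPR excluded) unless
    ``identity='id'``.
    """
    if kind == "gene":
        return element
    if kind == "metabolite":
        return element.id
    if kind == "reaction":
        if identity == "id":
            return element.id
        return reaction_signature(element)
    raise ValueError(f"unknown element kind {kind!r}")


def _element_keys(model: Model, kind: ElementKind, identity: IdentityMode, internal_only: bool) -> set:
    if kind == "gene":
        return set(model.genes)
    if kind == "metabolite":
        return {m.id for m in model.metabolites}
    rxns = model.reactions
    if internal_only:
        rxns = [r for r in rxns if classify_reaction(r, model) != "exchange"]
    return {element_key(r, "reaction", identity) for r in rxns}


def core_model(
    models: list[Model], identity: IdentityMode = "signature", model_id: str = "core"
) -> Model:
    """Intersection model: reactions whose key appears in every member.

    The first model's representative of each key is retained; bounds become
    the widest common interval ([max of lower bounds, min of upper bounds],
    the intersection of the members' feasible ranges).  Metabolites and
    genes are those induced by retained reactions.  An empty intersection
    yields a valid empty model.
    """
    if not models:
        raise ValueError("need at least one model")
    key_sets = [
        {element_key(r, "reaction", identity) for r in m.reactions} for m in models
    ]
    common = set.intersection(*key_sets)
    out = Model(id=model_id)
    first = models[0]
    for rxn in first.reactions:
        key = element_key(rxn, "reaction", identity)
        if key not in common:
            continue
        common.discard(key)  # keep first representative only
        new = rxn.copy()
        lo, hi = rxn.lower_bound, rxn.upper_bound
        for other in models[1:]:
            for r2 in other.reactions:
                if element_key(r2, "reaction", identity) == key or (
                    identity == "id" and r2.id == rxn.id
                ):
                    lo = max(lo, r2.lower_bound)
                    hi = min(hi, r2.upper_bound)
                    break
        new.lower_bound, new.upper_bound = min(lo, hi), hi
        for met_id in new.stoichiometry:
            if not out.has_metabolite(met_id):
                out.add_metabolite(first.metabolite(met_id).copy())
        out.add_reaction(new)
    out.genes = set.intersection(*(set(m.genes) for m in models)) & _induced_genes(out)
    return out


def _induced_genes(model: Model) -> set[str]:
    genes: set[str] = set()
    for r in model.reactions:
        genes |= r.genes()
    return genes or set(model.genes)


def pan_model(
    models: list[Model], identity: IdentityMode = "signature", model_id: str = "pan"
) -> Model:
    """Union model: the first-seen representative of every reaction key.

    Metabolites and genes are unioned; conflicting metabolite definitions
    under one id raise a reconciliation error.
    """
    if not models:
        raise ValueError("need at least one model")
    out = Model(id=model_id)
    seen: set = set()
    for m in models:
        for rxn in m.reactions:
            key = element_key(rxn, "reaction", identity)
            if key in seen:
                continue
            seen.add(key)
            for met_id in rxn.stoichiometry:
                _merge_met(out, m.metabolite(met_id))
            new = rxn.copy()
            if out.has_reaction(new.id):
                new.id = f"{new.id}__{m.id}"
            out.add_reaction(new)
        out.genes |= set(m.genes)
    return out


def _merge_met(model: Model, met: Metabolite) -> None:
    if not model.has_metabolite(met.id):
        model.add_metabolite(met.copy())
        return
    existing = model.metabolite(met.id)
    if (
        existing.formula is not None
        and met.formula is not None
        and existing.formula != met.formula
    ):
        raise ReconciliationError(
            f"metabolite {met.id!r} has conflicting formulas across panel members"
        )


@dataclass
class ElementClassification:
    """Common/dispensable/specific partition over the union of group pans."""

    kind: ElementKind
    common: set
    dispensable: set
    specific: dict[str, set]  # group label -> elements specific to it
    union_size: int

    @property
    def specific_all(self) -> set:
        out: set = set()
        for s in self.specific.values():
            out |= s
        return out

    def percentages(self) -> dict[str, float]:
        """Common/dispensable/specific as % of the union size."""
        if self.union_size == 0:
            return {"common": 0.0, "dispensable": 0.0, "specific": 0.0}
        return {
            "common": 100.0 * len(self.common) / self.union_size,
            "dispensable": 100.0 * len(self.dispensable) / self.union_size,
            "specific": 100.0 * len(self.specific_all) / self.union_size,
        }


def classify_elements(
    panel: StrainPanel,
    kind: ElementKind,
    identity: IdentityMode = "signature",
    internal_only: bool = False,
) -> ElementClassification:
    """Classify elements as common/dispensable/specific across host groups.

    Per-group pan sets are formed first; classification is over the union
    of those sets, so percentages are relative to the union size.  Needs at
    least two groups.
    """
    groups = panel.groups
    if len(groups) < 2:
        raise ValidationError("classification needs at least two groups")
    group_sets: dict[str, set] = {}
    for g in groups:
        keys: set = set()
        for m in panel.models_in(g):
            keys |= _element_keys(m, kind, identity, internal_only)
        group_sets[g] = keys
    union: set = set()
    for s in group_sets.values():
        union |= s
    common: set = set()
    dispensable: set = set()
    specific: dict[str, set] = {g: set() for g in groups}
    for key in union:
        containing = [g for g in groups if key in group_sets[g]]
        if len(containing) == len(groups):
            common.add(key)
        elif len(containing) == 1:
            specific[containing[0]].add(key)
        else:
            dispensable.add(key)
    return ElementClassification(
        kind=kind,
        common=common,
        dispensable=dispensable,
        specific=specific,
        union_size=len(union),
    )


@dataclass
class GroupSummary:
    """Per-group size statistics and core/pan ratios.

    ``sizes`` maps group -> {kind: (mean, sd)} with sample SD (n-1
    denominator; a single-member group reports SD 0 by convention).
    ``core``/``pan`` map group -> {kind: size}; ``core_pan_pct`` maps
    group -> {kind: 100*core/pan}.
    """

    sizes: dict[str, dict[str, tuple[float, float]]]
    core: dict[str, dict[str, int]]
    pan: dict[str, dict[str, int]]
    core_pan_pct: dict[str, dict[str, float]]
    n_strains: dict[str, int]


def group_summary(panel: StrainPanel, identity: IdentityMode = "signature") -> GroupSummary:
    """Mean +/- SD model sizes, core/pan sizes and core-to-pan percentages
    per host group, for reactions, metabolites and genes."""
    kinds: tuple[ElementKind, ...] = ("reaction", "metabolite", "gene")
    sizes: dict[str, dict[str, tuple[float, float]]] = {}
    core: dict[str, dict[str, int]] = {}
    pan: dict[str, dict[str, int]] = {}
    pct: dict[str, dict[str, float]] = {}
    n_strains: dict[str, int] = {}
    for g in panel.groups:
        models = panel.models_in(g)
        n_strains[g] = len(models)
        sizes[g] = {}
        core[g] = {}
        pan[g] = {}
        pct[g] = {}
        for kind in kinds:
            counts = np.array(
                [len(_element_keys(m, kind, identity, False)) for m in models], dtype=float
            )
            sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
            sizes[g][kind] = (float(np.mean(counts)), sd)
            key_sets = [_element_keys(m, kind, identity, False) for m in models]
            core_keys = set.intersection(*key_sets)
            pan_keys = set.union(*key_sets)
            core[g][kind] = len(core_keys)
            pan[g][kind] = len(pan_keys)
            pct[g][kind] = 100.0 * len(core_keys) / len(pan_keys) if pan_keys else math.nan
    return GroupSummary(sizes=sizes, core=core, pan=pan, core_pan_pct=pct, n_strains=n_strains)
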