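"""Template-based draft reconstruction.

The pipeline mirrors the template-based strategy used for lactic acid
bacteria: a primary template model contributes every reaction whose GPR is
satisfied by the ortholog-mapped genes; secondary templates are integrated
one by one in a fixed priority order (earlier templates win on conflicts);
exchange and transport reactions are added for the target growth medium;
and the biomass reaction is adopted from a template with the DNA term
recomputed from the target genome's GC content.

Reactions are identified across templates by a direction-normalized
stoichiometric signature (shared BiGG-style metabolite namespace assumed,
with an explicit synonym table for mismatches), never by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, ReconciliationError, ValidationError
from .gpr import GPR
from .media import MediumSpec
from .model import Metabolite, Model, Reaction, classify_reaction, reaction_signature

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "DnaComposition",
    "BiomassSpec",
    "DNMP_MOLAR_MASS",
    "build_draft",
    "integrate_template",
    "add_exchanges_and_transport",
    "dna_biomass_coefficients",
    "assemble_biomass",
    "apply_patch",
]

#: Molar masses (g/mol) of the free-acid deoxyribonucleoside monophosphates.
DNMP_MOLAR_MASS = {
    "damp": 331.22,
    "dcmp": 307.20,
    "dgmp": 347.22,
    "dtmp": 322.21,
}

#: Default DNA mass fraction of cell dry weight (g/gDW).
DNA_MASS_FRACTION = 0.031


@dataclass
class TemplateSet:
    """An ordered list of (template model, target-gene -> template-gene map).

    The first entry is the primary template; order is the integration
    priority and is significant.
    """

    entries: list[tuple[Model, dict[str, str]]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("TemplateSet needs at least one template")
        for template, mapping in self.entries:
            unknown = set(mapping.values()) - template.genes
            if unknown:
                raise ConfigurationError(
                    f"ortholog map for template {template.id!r} cites genes not in the "
                    f"template: {sorted(unknown)[:5]}"
                )

    @property
    def primary(self) -> tuple[Model, dict[str, str]]:
        return self.entries[0]


def _invert(ortholog_map: dict[str, str]) -> dict[str, str]:
    """target->template map inverted to template->target for GPR rewriting."""
    return {tpl: tgt for tgt, tpl in ortholog_map.items()}


def _merge_metabolite(model: Model, met: Metabolite) -> None:
    """Add a metabolite, or verify the existing definition is compatible."""
    if not model.has_metabolite(met.id):
        model.add_metabolite(met.copy())
        return
    existing = model.metabolite(met.id)
    if (
        existing.formula is not None
        and met.formula is not None
        and existing.formula != met.formula
    ) or (
        existing.charge is not None
        and met.charge is not None
        and existing.charge != met.charge
    ):
        raise ReconciliationError(
            f"metabolite {met.id!r} defined incompatibly across templates: "
            f"({existing.formula}, charge {existing.charge}) vs "
            f"({met.formula}, charge {met.charge})"
        )
    # fill gaps from the later definition
    if existing.formula is None and met.formula is not None:
        existing.formula = dict(met.formula)
    if existing.charge is None and met.charge is not None:
        existing.charge = met.charge
    for db, ident in met.annotations.items():
        existing.annotations.setdefault(db, ident)


def build_draft(
    primary: Model,
    ortholog_map: dict[str, str],
    draft_id: str = "draft",
    include_spontaneous: bool = True,
) -> Model:
    """Extract the draft model: template reactions whose GPR is satisfied
    when exactly the mapped template genes are present.

    GPR leaves are rewritten to target-organism gene ids, with unmapped
    OR-branches pruned.  Reactions with no gene association count as
    satisfied (spontaneous/diffusion steps, the biomass reaction) and are
    carried unless ``include_spontaneous`` is off; exchange reactions are
    never carried here — they are re-added per medium and secretion needs
    by :func:`add_exchanges_and_transport`.
    """
    if not ortholog_map:
        logger.warning("empty ortholog map: draft for %r carries only spontaneous reactions", draft_id)
    rewrite = _invert(ortholog_map)
    present = set(rewrite)  # template genes with an ortholog
    draft = Model(id=draft_id)
    for rxn in primary.reactions:
        if classify_reaction(rxn, primary) == "exchange":
            continue
        if rxn.gpr is None:
            if not include_spontaneous:
                continue
            new_gpr = None
        else:
            if not rxn.gpr.evaluate(present):
                continue
            new_gpr = rxn.gpr.rewrite(rewrite)
        for met_id in rxn.stoichiometry:
            _merge_metabolite(draft, primary.metabolite(met_id))
        new_rxn = rxn.copy()
        new_rxn.gpr = new_gpr
        draft.add_reaction(new_rxn)
    draft.genes |= set(ortholog_map)
    return draft


def integrate_template(
    draft: Model,
    template: Model,
    ortholog_map: dict[str, str],
) -> Model:
    """Add template reactions that are GPR-satisfiable under the map and
    whose stoichiometric signature is not already in the draft.

    Existing reactions are never overwritten, so earlier templates take
    precedence; re-applying the same template is a no-op.
    """
    rewrite = _invert(ortholog_map)
    present = set(rewrite)
    out = draft.copy()
    existing_sigs = {reaction_signature(r) for r in out.reactions}
    added = 0
    for rxn in template.reactions:
        if rxn.gpr is None or not rxn.gpr.evaluate(present):
            continue
        sig = reaction_signature(rxn)
        if sig in existing_sigs:
            continue
        for met_id in rxn.stoichiometry:
            _merge_metabolite(out, template.metabolite(met_id))
        new_rxn = rxn.copy()
        new_rxn.gpr = rxn.gpr.rewrite(rewrite)
        if out.has_reaction(new_rxn.id):
            new_rxn.id = f"{new_rxn.id}__{template.id}"
        out.add_reaction(new_rxn)
        existing_sigs.add(sig)
        added += 1
    out.genes |= set(ortholog_map)
    logger.info("integrated %d reactions from template %r", added, template.id)
    return out


def add_exchanges_and_transport(
    model: Model,
    medium: MediumSpec,
    templates: Sequence[tuple[Model, dict[str, str]]] = (),
    diffusible: Iterable[str] = (),
    secretion_upper: float = 1000.0,
) -> Model:
    """Ensure every medium metabolite has an exchange reaction (lower bound
    -(max uptake)) and, where possible, a transport route into the cytosol.

    Transport reactions are copied from the first template (in priority
    order) that supplies a GPR-satisfiable transporter for the metabolite;
    metabolites flagged ``diffusible`` get a plain diffusion reaction.  A
    medium metabolite with neither is retained but flux-blocked, with a
    warning.  Every other extracellular metabolite of the model gets a
    secretion-only exchange (lower bound 0) so by-products can leave.
    """
    out = model.copy()
    diffusible = set(diffusible)
    for met_id in sorted(medium.uptake_rates):
        rate = medium.uptake_rates[met_id]
        if not met_id.endswith("_e"):
            raise ValidationError(f"medium metabolite {met_id!r} is not extracellular ('_e')")
        if not out.has_metabolite(met_id):
            out.add_metabolite(Metabolite(met_id, name=met_id[:-2], compartment="e"))
        ex = out.exchange_for(met_id)
        if ex is None:
            ex = Reaction(
                f"EX_{met_id}",
                name=f"{met_id[:-2]} exchange",
                stoichiometry={met_id: -1.0},
                lower_bound=-abs(rate),
                upper_bound=secretion_upper,
            )
            if out.has_reaction(ex.id):
                ex.id += "_x"
            out.add_reaction(ex)
        else:
            ex.lower_bound = -abs(rate)

        if _has_transport(out, met_id):
            continue
        transporter = _template_transporter(templates, met_id)
        if transporter is not None:
            rxn, rewrite = transporter
            new_rxn = rxn.copy()
            new_rxn.gpr = rxn.gpr.rewrite(rewrite) if rxn.gpr is not None else None
            for m in new_rxn.stoichiometry:
                src = next(t for t, _ in templates if t.has_metabolite(m))
                _merge_metabolite(out, src.metabolite(m))
            if out.has_reaction(new_rxn.id):
                new_rxn.id += "_t"
            out.add_reaction(new_rxn)
        elif met_id in diffusible:
            cyt = met_id[:-2] + "_c"
            if not out.has_metabolite(cyt):
                out.add_metabolite(Metabolite(cyt, name=met_id[:-2], compartment="c"))
            out.add_reaction(
                Reaction(
                    f"{met_id[:-2].upper()}t_diff",
                    name=f"{met_id[:-2]} diffusion",
                    stoichiometry={met_id: -1.0, cyt: 1.0},
                    lower_bound=-1000.0,
                    upper_bound=1000.0,
                )
            )
        else:
            logger.warning(
                "medium metabolite %r has no transport route and is not diffusible; "
                "uptake will be flux-blocked",
                met_id,
            )
    # secretion-only exchanges for remaining extracellular metabolites
    for met in list(out.metabolites):
        if met.compartment != "e" or out.exchange_for(met.id) is not None:
            continue
        ex = Reaction(
            f"EX_{met.id}",
            name=f"{met.id[:-2] if met.id.endswith('_e') else met.id} exchange",
            stoichiometry={met.id: -1.0},
            lower_bound=0.0,
            upper_bound=secretion_upper,
        )
        if out.has_reaction(ex.id):
            ex.id += "_x"
        out.add_reaction(ex)
    return out


def _has_transport(model: Model, met_e: str) -> bool:
    for rxn in model.reactions:
        if met_e in rxn.stoichiometry and classify_reaction(rxn, model) == "transport":
            return True
    return False


def _template_transporter(
    templates: Sequence[tuple[Model, dict[str, str]]], met_e: str
) -> Optional[tuple[Reaction, dict[str, str]]]:
    for template, ortholog_map in templates:
        rewrite = _invert(ortholog_map)
        present = set(rewrite)
        if not template.has_metabolite(met_e):
            continue
        for rxn in template.reactions:
            if met_e not in rxn.stoichiometry:
                continue
            if classify_reaction(rxn, template) != "transport":
                continue
            if rxn.gpr is not None and not rxn.gpr.evaluate(present):
                continue
            return rxn, rewrite
    return None


# ---------------------------------------------------------------------------
# biomass


@dataclass
class DnaComposition:
    """GC-derived dNMP biomass coefficients.

    Mole fractions follow base pairing: A = T = (1-gc)/2, G = C = gc/2.
    Per-dNMP coefficients (mmol/gDW) are scaled so the mass-weighted sum
    equals ``dna_mass_fraction`` (g DNA per g dry weight).
    """

    gc_content: float
    dna_mass_fraction: float = DNA_MASS_FRACTION
    coefficients: dict[str, float] = field(default_factory=dict)


def dna_biomass_coefficients(
    gc_content: float, dna_mass_fraction: float = DNA_MASS_FRACTION
) -> DnaComposition:
    """Compute per-dNMP biomass coefficients from genome GC content.

    coefficient_i = 1000 * x_i * D / sum_j(x_j * M_j), with x the mole
    fractions, D the DNA mass fraction (g/gDW) and M the dNMP molar masses
    (g/mol); coefficients come out in mmol/gDW and satisfy
    sum_i coefficient_i * M_i / 1000 == D.
    """
    if not (0.0 <= gc_content <= 1.0):
        raise ValueError(f"GC content must be in [0,1], got {gc_content}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    fractions = {"damp": at, "dtmp": at, "dgmp": gc, "dcmp": gc}
    mean_mass = sum(fractions[n] * DNMP_MOLAR_MASS[n] for n in fractions)
    coeffs = {
        n: 1000.0 * fractions[n] * dna_mass_fraction / mean_mass for n in sorted(fractions)
    }
    return DnaComposition(
        gc_content=gc_content, dna_mass_fraction=dna_mass_fraction, coefficients=coeffs
    )


@dataclass
class BiomassSpec:
    """Macromolecular biomass composition adopted from a template.

    ``classes`` maps a macromolecule class (protein, dna, lipid, ...) to
    (mass fraction g/gDW, {metabolite id: coefficient mmol/gDW}).
    Coefficients are negative-free; consumption signs are applied when the
    reaction is assembled.
    """

    source_template: str
    classes: dict[str, tuple[float, dict[str, float]]]
    atp_maintenance: float = 10.0  # mmol ATP/gDW hydrolysed per unit biomass
    biomass_metabolite: str = "biomass_c"


def assemble_biomass(
    template_biomass: BiomassSpec,
    dna: DnaComposition,
    overrides: Optional[dict[str, float]] = None,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Build the biomass reaction from a template composition.

    The DNA class is replaced by the four GC-derived dNMP coefficients;
    ``overrides`` scales the component coefficients of named classes (e.g.
    ``{"protein": 1.1}``).  The reaction consumes precursors and ATP and
    produces one unit of the biomass pseudo-metabolite.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(template_biomass.classes)
    if unknown:
        raise ConfigurationError(
            f"biomass override names unknown classes: {sorted(unknown)}; "
            f"known: {sorted(template_biomass.classes)}"
        )
    stoich: dict[str, float] = {}
    for cls, (fraction, components) in template_biomass.classes.items():
        if fraction <= 0:
            raise ValidationError(f"biomass class {cls!r} has non-positive mass fraction")
        if cls == "dna":
            comps = {f"{n}_c": coeff for n, coeff in dna.coefficients.items()}
        else:
            comps = dict(components)
        scale = overrides.get(cls, 1.0)
        for met_id, coeff in comps.items():
            stoich[met_id] = stoich.get(met_id, 0.0) - scale * coeff
    if template_biomass.atp_maintenance:
        stoich["atp_c"] = stoich.get("atp_c", 0.0) - template_biomass.atp_maintenance
        stoich["adp_c"] = stoich.get("adp_c", 0.0) + template_biomass.atp_maintenance
    stoich[template_biomass.biomass_metabolite] = 1.0
    return Reaction(
        reaction_id,
        name="biomass assembly",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
    )


# ---------------------------------------------------------------------------
# curation patches


def apply_patch(model: Model, patch: dict) -> Model:
    """Apply a declarative curation patch: reproducible manual curation.

    Patch schema (YAML-friendly)::

        add_metabolites: [{id, name, compartment, formula, charge}]
        add_reactions:   [{id, stoichiometry: {met: coeff}, lower_bound,
                           upper_bound, gpr}]
        remove_reactions: [reaction_id, ...]
    """
    from .gpr import parse_gpr
    from .model import parse_formula

    out = model.copy()
    for spec in patch.get("add_metabolites", []):
        if not out.has_metabolite(spec["id"]):
            out.add_metabolite(
                Metabolite(
                    id=spec["id"],
                    name=spec.get("name", ""),
                    compartment=spec.get("compartment", spec["id"].rsplit("_", 1)[-1]),
                    formula=parse_formula(spec["formula"]) if spec.get("formula") else None,
                    charge=spec.get("charge"),
                )
            )
    for spec in patch.get("add_reactions", []):
        rxn = Reaction(
            id=spec["id"],
            name=spec.get("name", ""),
            stoichiometry={k: float(v) for k, v in spec["stoichiometry"].items()},
            lower_bound=float(spec.get("lower_bound", 0.0)),
            upper_bound=float(spec.get("upper_bound", 1000.0)),
            gpr=parse_gpr(spec["gpr"]) if spec.get("gpr") else None,
        )
        rxn.annotations["provenance"] = "curation"
        for g in rxn.genes():
            out.genes.add(g)
        out.add_reaction(rxn)
    for rid in patch.get("remove_reactions", []):
        out.remove_reaction(rid)
    return out
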