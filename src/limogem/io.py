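"""Model readers and writers: SBML Level 3 + FBC v2, and a JSON mirror.

SBML is written with the community ``M_``/``R_``/``G_`` id prefixes so that
files interoperate with other COBRA tooling; prefixes are stripped on read.
Database cross-references (MetaCyc, KEGG, MetaNetX, ...) are stored as
identifiers.org resource URIs in RDF annotations.

The JSON dialect is a plain structural mirror of :class:`~limogem.model.Model`
used for tests and light-weight pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import libsbml

from .errors import FormatError, IntegrityError, ValidationError
from .gpr import GPR, gene_leaf, gpr_and, gpr_or, parse_gpr
from .model import COMPARTMENTS, Metabolite, Model, Reaction, formula_to_string, parse_formula

__all__ = ["read_model", "write_model"]

_IDENTIFIERS_ORG = "https://identifiers.org/"


def read_model(path: Union[str, Path], dialect: str = "sbml_fbc") -> Model:
    """Read a model file under the named dialect (``sbml_fbc`` or ``json``).

    The returned model satisfies all structural invariants; bounds, GPRs,
    formulas, charges and annotations are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if dialect == "sbml_fbc":
        model = _read_sbml(path)
    elif dialect == "json":
        model = _read_json(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        model.validate()
    except (ValidationError, IntegrityError) as exc:
        raise IntegrityError(f"{path}: {exc}") from exc
    return model


def write_model(model: Model, path: Union[str, Path], dialect: str = "sbml_fbc") -> None:
    """Write a model; refuses (raising) if the model violates an invariant.

    Output is byte-stable: writing the same model twice produces identical
    files.
    """
    model.validate()
    path = Path(path)
    if dialect == "sbml_fbc":
        path.write_text(_to_sbml_string(model))
    elif dialect == "json":
        path.write_text(_to_json_string(model))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# JSON dialect


def _to_json_string(model: Model) -> str:
    doc = {
        "id": model.id,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": formula_to_string(m.formula) if m.formula is not None else None,
                "charge": m.charge,
                "annotations": dict(sorted(m.annotations.items())),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "annotations": dict(sorted(r.annotations.items())),
            }
            for r in model.reactions
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
        "objective_reaction_id": model.objective_reaction_id,
    }
    return json.dumps(doc, indent=1) + "\n"


def _read_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=parse_formula(m["formula"]) if m.get("formula") else None,
                charge=m.get("charge"),
                annotations=dict(m.get("annotations", {})),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r["gpr"]) if r.get("gpr") else None,
                annotations=dict(r.get("annotations", {})),
            )
            for r in doc["reactions"]
        ]
    except KeyError as exc:
        raise FormatError(f"{path}: missing required field {exc}") from exc
    return Model(
        id=doc.get("id", path.stem),
        metabolites=mets,
        reactions=rxns,
        genes=set(doc.get("genes", [])),
        biomass_reaction_id=doc.get("biomass_reaction_id"),
        objective_reaction_id=doc.get("objective_reaction_id"),
    )


# ---------------------------------------------------------------------------
# SBML L3V1 + FBC v2


def _annotate(element, meta_id: str, annotations: dict[str, str]) -> None:
    if not annotations:
        return
    element.setMetaId(meta_id)
    for db in sorted(annotations):
        cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(libsbml.BQB_IS)
        cv.addResource(f"{_IDENTIFIERS_ORG}{db}/{annotations[db]}")
        element.addCVTerm(cv)


def _read_annotations(element) -> dict[str, str]:
    out: dict[str, str] = {}
    for i in range(element.getNumCVTerms()):
        cv = element.getCVTerm(i)
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            if _IDENTIFIERS_ORG in uri:
                tail = uri.split(_IDENTIFIERS_ORG, 1)[1]
                if "/" in tail:
                    db, ident = tail.split("/", 1)
                    out[db] = ident
    return out


def _build_association(parent, node: GPR) -> None:
    if node.op == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct("G_" + node.gene)
    elif node.op == "and":
        fand = parent.createAnd()
        for child in node.children:
            _build_association(fand, child)
    else:
        f_or = parent.createOr()
        for child in node.children:
            _build_association(f_or, child)


def _parse_association(assoc) -> GPR:
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return gene_leaf(gid[2:] if gid.startswith("G_") else gid)
    children = [_parse_association(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    if assoc.isFbcAnd():
        return gpr_and(children)
    if assoc.isFbcOr():
        return gpr_or(children)
    raise FormatError("unsupported gene association node")


def _to_sbml_string(model: Model) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for suffix, name in COMPARTMENTS.items():
        comp = sm.createCompartment()
        comp.setId(suffix)
        comp.setName(name)
        comp.setConstant(True)

    # one shared constant parameter per distinct bound value, in first-use order
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(met.charge)
        if met.formula is not None:
            splug.setChemicalFormula(formula_to_string(met.formula))
        _annotate(sp, "meta_M_" + met.id, met.annotations)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId("G_" + gene)
        gp.setLabel(gene)

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId("R_" + rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met_id]
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr)
        _annotate(sr, "meta_R_" + rxn.id, rxn.annotations)

    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
    if model.biomass_reaction_id is not None and model.biomass_reaction_id != model.objective_reaction_id:
        obj = mplug.createObjective()
        obj.setId("biomass_marker")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.biomass_reaction_id)
        fo.setCoefficient(1.0)

    return libsbml.writeSBMLToString(doc)


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: Path) -> Model:
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise FormatError(
                f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path}: document contains no model")
    mplug = sm.getPlugin("fbc")

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    mets: list[Metabolite] = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        charge = None
        formula = None
        if splug is not None:
            if splug.isSetCharge():
                charge = splug.getCharge()
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
        mets.append(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName() or "",
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotations=_read_annotations(sp),
            )
        )

    genes: set[str] = set()
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            genes.add(gp.getLabel() or _strip("G_", gp.getId()))

    rxns: list[Reaction] = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gpr = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                pid = rplug.getLowerFluxBound()
                if pid not in params:
                    raise FormatError(f"{path}: reaction {sr.getId()} cites missing parameter {pid!r}")
                lb = params[pid]
            if rplug.isSetUpperFluxBound():
                pid = rplug.getUpperFluxBound()
                if pid not in params:
                    raise FormatError(f"{path}: reaction {sr.getId()} cites missing parameter {pid!r}")
                ub = params[pid]
            if rplug.isSetGeneProductAssociation():
                gpr = _parse_association(rplug.getGeneProductAssociation().getAssociation())
        rxns.append(
            Reaction(
                id=_strip("R_", sr.getId()),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                annotations=_read_annotations(sr),
            )
        )

    objective_id: Optional[str] = None
    biomass_id: Optional[str] = None
    if mplug is not None:
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getNumFluxObjectives() == 0:
                continue
            target = _strip("R_", obj.getFluxObjective(0).getReaction())
            if obj.getId() == "biomass_marker":
                biomass_id = target
            elif objective_id is None or obj.getId() == mplug.getActiveObjectiveId():
                objective_id = target
    if biomass_id is None:
        biomass_id = objective_id

    return Model(
        id=sm.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        biomass_reaction_id=biomass_id,
        objective_reaction_id=objective_id,
    )
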