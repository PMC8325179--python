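"""Synthetic fixtures: template networks, hit tables and strain panels.

The generator emulates the inputs of a template-based reconstruction study
of heterofermentative lactobacilli:

* a toy template network containing both glycolytic branches — the
  Embden–Meyerhof–Parnas (EMP) route through phosphofructokinase (PFK) and
  fructose-1,6-bisphosphate aldolase (FBA), and the phosphoketolase (PK)
  route — fermentation end-products (lactate, acetate, ethanol), histidine
  decarboxylation to histamine, glycerol -> 3-HPA -> 1,3-propanediol, and
  vitamin (folate, cobalamin) and 1-propanol stubs.  ATP stoichiometry is
  fixed so EMP yields 2 ATP per glucose and PK 1, making EMP-capped growth
  drop but stay positive via the PK branch;
* BLASTP-style hit tables with planted reciprocal orthologs above the
  filtering thresholds and noise hits below them;
* host-group strain panels (herbivore/omnivore/sourdough) with
  group-specific pathway presence probabilities and planted amino-acid
  auxotrophies, each with machine-readable ground truth.

Pathway stubs are 1–3 reaction abstractions, not full database pathways:
the fixtures exercise pipeline logic, not biochemistry completeness.
Every generated model is validated and must grow on its reference medium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import GenerationError
from .gpr import gene_leaf, gpr_and, gpr_or, parse_gpr
from .media import AMINO_ACIDS, MediumSpec, reference_medium
from .model import Metabolite, Model, Reaction
from .orthology import HitRecord, ThresholdSet
from .pancore import StrainPanel
from .reconstruct import BiomassSpec, assemble_biomass, dna_biomass_coefficients
from .simulate import growth_with_cap, production_capability

__all__ = [
    "PATHWAYS",
    "PRODUCTS",
    "PRODUCT_METABOLITES",
    "NetworkSpec",
    "PanelSpec",
    "GroupSpec",
    "TemplateGroundTruth",
    "StrainGroundTruth",
    "make_template_network",
    "make_hit_tables",
    "make_strain_panel",
    "write_hit_table",
    "capability_medium",
    "capability_matrix",
    "panel_ground_truth_json",
]

#: Optional pathway modules of the template network.
PATHWAYS = (
    "EMP",
    "PK",
    "lactate",
    "acetate",
    "ethanol",
    "histamine",
    "glycerol_3HPA_PDO",
    "folate",
    "cobalamin",
    "propanol",
)

#: The eight screened products, in reporting order.
PRODUCTS = (
    "lactate",
    "acetate",
    "ethanol",
    "histamine",
    "folate",
    "cobalamin",
    "1-propanol",
    "1,3-propanediol",
)

PRODUCT_METABOLITES = {
    "lactate": "lac_e",
    "acetate": "ac_e",
    "ethanol": "etoh_e",
    "histamine": "hista_e",
    "folate": "fol_e",
    "cobalamin": "cbl_e",
    "1-propanol": "1poh_e",
    "1,3-propanediol": "13pdo_e",
}

#: Pathway module enabling each product.
_PRODUCT_PATHWAY = {
    "lactate": "lactate",
    "acetate": "acetate",
    "ethanol": "ethanol",
    "histamine": "histamine",
    "folate": "folate",
    "cobalamin": "cobalamin",
    "1-propanol": "propanol",
    "1,3-propanediol": "glycerol_3HPA_PDO",
}

#: Products additionally requiring the PK branch (acetyl-phosphate supply).
_NEEDS_PK = {"acetate", "ethanol"}


def capability_medium() -> MediumSpec:
    """Medium for product-capability screens: the reference chemically
    defined medium plus glycerol (the 1,3-propanediol precursor)."""
    return reference_medium(glycerol=True)


@dataclass
class NetworkSpec:
    """What the template network should contain."""

    pathways: dict[str, bool] = field(default_factory=lambda: {p: True for p in PATHWAYS})
    auxotrophies: tuple[str, ...] = ()  # amino acids without a synthesis route
    gc_content: float = 0.39
    model_id: str = "template"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.pathways) - set(PATHWAYS)
        if unknown:
            raise ValueError(f"unknown pathway flags: {sorted(unknown)}")
        for p in PATHWAYS:
            self.pathways.setdefault(p, False)
        bad = set(self.auxotrophies) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown amino acids: {sorted(bad)}")


@dataclass
class TemplateGroundTruth:
    """Machine-readable ground truth for a generated template."""

    pathway_reactions: dict[str, list[str]]
    genes: list[str]
    gene_reactions: dict[str, list[str]]
    auxotrophies: list[str]
    gc_content: float


class _Builder:
    """Accumulates a model, assigning SYN_#### gene ids in creation order."""

    def __init__(self, model_id: str) -> None:
        self.model = Model(id=model_id)
        self._gene_counter = 0
        self.gene_reactions: dict[str, list[str]] = {}
        self.pathway_reactions: dict[str, list[str]] = {}

    def gene(self) -> str:
        self._gene_counter += 1
        return f"SYN_{self._gene_counter:04d}"

    def met(self, met_id: str, name: str = "") -> None:
        if not self.model.has_metabolite(met_id):
            comp = met_id.rsplit("_", 1)[-1]
            self.model.add_metabolite(Metabolite(met_id, name=name or met_id[:-2], compartment=comp))

    def rxn(
        self,
        rid: str,
        stoich: dict[str, float],
        lb: float = 0.0,
        ub: float = 1000.0,
        n_genes: int = 1,
        gpr_shape: str = "single",
        pathway: str = "core",
        name: str = "",
    ) -> None:
        for m in stoich:
            self.met(m)
        gpr = None
        if n_genes > 0:
            genes = [self.gene() for _ in range(n_genes)]
            leaves = [gene_leaf(g) for g in genes]
            gpr = leaves[0] if n_genes == 1 else (gpr_and(leaves) if gpr_shape == "and" else gpr_or(leaves))
            for g in genes:
                self.model.genes.add(g)
                self.gene_reactions.setdefault(g, []).append(rid)
        self.model.add_reaction(
            Reaction(rid, name=name, stoichiometry=stoich, lower_bound=lb, upper_bound=ub, gpr=gpr)
        )
        self.pathway_reactions.setdefault(pathway, []).append(rid)


def make_template_network(spec: Optional[NetworkSpec] = None) -> tuple[Model, TemplateGroundTruth]:
    """Generate the template network and its ground truth.

    The model always carries glucose uptake, lumped lower glycolysis, a
    water-forming NADH oxidase (redox valve), amino-acid transport, dNMP
    synthesis and a GC-derived biomass reaction; pathway flags switch the
    two glycolytic branches and the product modules.  Generation fails if
    no glycolytic branch is enabled.
    """
    spec = spec or NetworkSpec()
    on = spec.pathways
    if not (on["EMP"] or on["PK"]):
        raise GenerationError("at least one glycolytic branch (EMP or PK) must be enabled")
    needs_pk = any(on[_PRODUCT_PATHWAY[p]] for p in _NEEDS_PK)
    if needs_pk and not on["PK"]:
        raise GenerationError("acetate/ethanol modules need the PK branch (acetyl phosphate)")

    b = _Builder(spec.model_id)

    # -- glucose uptake and upper glycolysis (core) -------------------------
    b.rxn("EX_glc_e", {"glc_e": -1}, lb=-25.0, n_genes=0, name="glucose exchange")
    b.rxn("GLCt", {"glc_e": -1, "glc_c": 1}, n_genes=1, name="glucose transport")
    b.rxn("HEX1", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, n_genes=1, name="hexokinase")
    b.rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, lb=-1000.0, n_genes=1, name="phosphoglucose isomerase")
    # lumped lower glycolysis: GAP -> pyruvate with 2 substrate-level ATP
    b.rxn(
        "GLYCL",
        {"g3p_c": -1, "adp_c": -2, "nad_c": -1, "pyr_c": 1, "atp_c": 2, "nadh_c": 1},
        n_genes=1,
        name="lower glycolysis (lumped)",
    )
    b.rxn("NOX", {"nadh_c": -1, "nad_c": 1}, n_genes=1, name="NADH oxidase (water-forming)")
    # non-growth-associated maintenance: free ATP sink so that secretion
    # screens are decoupled from biomass precursor drains
    b.rxn("ATPM", {"atp_c": -1, "adp_c": 1}, n_genes=0, name="ATP maintenance")
    b.rxn("CO2t", {"co2_c": -1, "co2_e": 1}, lb=-1000.0, n_genes=0, name="CO2 diffusion")
    b.rxn("EX_co2_e", {"co2_e": -1}, n_genes=0, name="CO2 exchange")

    if on["EMP"]:
        # PFK gets two isozyme genes (OR) to exercise GPR logic
        b.rxn(
            "PFK",
            {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1},
            n_genes=2,
            gpr_shape="or",
            pathway="EMP",
            name="phosphofructokinase",
        )
        b.rxn("FBA", {"fdp_c": -1, "g3p_c": 2}, pathway="EMP", name="fructose-bisphosphate aldolase")
    if on["PK"]:
        b.rxn(
            "GND",
            {"g6p_c": -1, "nad_c": -1, "xu5p_c": 1, "co2_c": 1, "nadh_c": 1},
            pathway="PK",
            name="oxidative branch (lumped) to xylulose-5-P",
        )
        b.rxn(
            "PKT",
            {"xu5p_c": -1, "g3p_c": 1, "actp_c": 1},
            pathway="PK",
            name="phosphoketolase",
        )

    # -- fermentation end-products ------------------------------------------
    if on["lactate"]:
        b.rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1}, pathway="lactate", name="lactate dehydrogenase")
        b.rxn("LACt", {"lac_c": -1, "lac_e": 1}, pathway="lactate", name="lactate transport")
        b.rxn("EX_lac_e", {"lac_e": -1}, n_genes=0, pathway="lactate")
    if on["acetate"]:
        b.rxn("ACK", {"actp_c": -1, "ac_c": 1}, pathway="acetate", name="acetyl-P to acetate")
        b.rxn("ACt", {"ac_c": -1, "ac_e": 1}, pathway="acetate", name="acetate transport")
        b.rxn("EX_ac_e", {"ac_e": -1}, n_genes=0, pathway="acetate")
    if on["ethanol"]:
        b.rxn(
            "ADHE",
            {"actp_c": -1, "nadh_c": -2, "etoh_c": 1, "nad_c": 2},
            n_genes=2,
            gpr_shape="and",
            pathway="ethanol",
            name="acetyl-P to ethanol (lumped)",
        )
        b.rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}, pathway="ethanol", name="ethanol transport")
        b.rxn("EX_etoh_e", {"etoh_e": -1}, n_genes=0, pathway="ethanol")

    # -- histidine decarboxylation to histamine ------------------------------
    if on["histamine"]:
        b.rxn(
            "HDC",
            {"his_c": -1, "hista_c": 1, "co2_c": 1},
            n_genes=2,
            gpr_shape="and",
            pathway="histamine",
            name="histidine decarboxylase (hdcA/hdcB)",
        )
        b.rxn("HISTAt", {"hista_c": -1, "hista_e": 1}, pathway="histamine", name="histidine/histamine antiporter")
        b.rxn("EX_hista_e", {"hista_e": -1}, n_genes=0, pathway="histamine")

    # -- glycerol -> 3-HPA -> 1,3-propanediol --------------------------------
    if on["glycerol_3HPA_PDO"]:
        b.rxn("EX_glyc_e", {"glyc_e": -1}, lb=-25.0, n_genes=0, pathway="glycerol_3HPA_PDO")
        b.rxn("GLYCt", {"glyc_e": -1, "glyc_c": 1}, pathway="glycerol_3HPA_PDO", name="glycerol transport")
        b.rxn(
            "GDHT",
            {"glyc_c": -1, "3hpa_c": 1},
            n_genes=3,
            gpr_shape="and",
            pathway="glycerol_3HPA_PDO",
            name="B12-dependent glycerol/diol dehydratase (pduCDE)",
        )
        b.rxn(
            "PDOR",
            {"3hpa_c": -1, "nadh_c": -1, "13pdo_c": 1, "nad_c": 1},
            pathway="glycerol_3HPA_PDO",
            name="1,3-propanediol oxidoreductase",
        )
        b.rxn("PDOt", {"13pdo_c": -1, "13pdo_e": 1}, pathway="glycerol_3HPA_PDO")
        b.rxn("EX_13pdo_e", {"13pdo_e": -1}, n_genes=0, pathway="glycerol_3HPA_PDO")

    # -- vitamin and alcohol stubs -------------------------------------------
    if on["folate"]:
        b.rxn("FOLS", {"g3p_c": -1, "atp_c": -1, "fol_c": 1, "adp_c": 1}, pathway="folate", name="folate synthesis (lumped)")
        b.rxn("FOLt", {"fol_c": -1, "fol_e": 1}, pathway="folate")
        b.rxn("EX_fol_e", {"fol_e": -1}, n_genes=0, pathway="folate")
    if on["cobalamin"]:
        b.rxn("CBLS", {"pyr_c": -1, "atp_c": -1, "cbl_c": 1, "adp_c": 1}, pathway="cobalamin", name="cobalamin synthesis (lumped)")
        b.rxn("CBLt", {"cbl_c": -1, "cbl_e": 1}, pathway="cobalamin")
        b.rxn("EX_cbl_e", {"cbl_e": -1}, n_genes=0, pathway="cobalamin")
    if on["propanol"]:
        b.rxn(
            "PPOHS",
            {"pyr_c": -1, "nadh_c": -2, "1poh_c": 1, "nad_c": 2},
            pathway="propanol",
            name="1-propanol synthesis (lumped, methylglyoxal route)",
        )
        b.rxn("PPOHt", {"1poh_c": -1, "1poh_e": 1}, pathway="propanol")
        b.rxn("EX_1poh_e", {"1poh_e": -1}, n_genes=0, pathway="propanol")

    # -- amino acids: uptake always, synthesis unless auxotrophic ------------
    for aa in AMINO_ACIDS:
        b.rxn(f"EX_{aa}_e", {f"{aa}_e": -1}, lb=-5.0, n_genes=0, pathway="core")
        b.rxn(f"{aa.upper()}t", {f"{aa}_e": -1, f"{aa}_c": 1}, pathway="core", name=f"{aa} transport")
        if aa not in spec.auxotrophies:
            b.rxn(
                f"SYNTH_{aa}",
                {"pyr_c": -1, "atp_c": -1, f"{aa}_c": 1, "adp_c": 1},
                pathway="core",
                name=f"{aa} biosynthesis (lumped)",
            )

    # -- dNMPs and biomass ----------------------------------------------------
    for n in ("damp", "dcmp", "dgmp", "dtmp"):
        b.rxn(
            f"DNMPS_{n}",
            {"g3p_c": -1, "atp_c": -1, f"{n}_c": 1, "adp_c": 1},
            pathway="core",
            name=f"{n} synthesis (lumped)",
        )
    dna = dna_biomass_coefficients(spec.gc_content)
    biomass_spec = BiomassSpec(
        source_template=spec.model_id,
        classes={
            "protein": (0.55, {f"{aa}_c": 0.2 for aa in AMINO_ACIDS}),
            "dna": (dna.dna_mass_fraction, {}),
        },
    )
    biomass = assemble_biomass(biomass_spec, dna)
    for m in biomass.stoichiometry:
        b.met(m)
    b.model.add_reaction(biomass)
    b.pathway_reactions.setdefault("core", []).append(biomass.id)
    b.rxn("DM_biomass", {"biomass_c": -1}, n_genes=0, name="biomass drain")

    model = b.model
    model.biomass_reaction_id = biomass.id
    model.objective_reaction_id = biomass.id
    model.validate()
    medium = reference_medium(glycerol=on["glycerol_3HPA_PDO"])
    verdict = growth_with_cap(model, medium)
    if not verdict.grows:
        raise GenerationError(f"generated template {model.id!r} does not grow on its reference medium")

    truth = TemplateGroundTruth(
        pathway_reactions={k: list(v) for k, v in b.pathway_reactions.items()},
        genes=sorted(model.genes),
        gene_reactions={g: list(rs) for g, rs in sorted(b.gene_reactions.items())},
        auxotrophies=list(spec.auxotrophies),
        gc_content=spec.gc_content,
    )
    return model, truth


# ---------------------------------------------------------------------------
# hit tables


def make_hit_tables(
    template_genes: list[str],
    retention_prob: float = 0.6,
    noise_hits: int = 50,
    seed: int = 0,
    target_prefix: str = "ORG_",
    thresholds: ThresholdSet = ThresholdSet(),
) -> tuple[list[HitRecord], list[HitRecord], dict[str, str]]:
    """Two reciprocal hit tables with planted orthologs and sub-threshold noise.

    Each template gene is retained with probability ``retention_prob``;
    retained genes get reciprocal above-threshold hits to a renamed target
    gene.  Noise hits each violate at least one filtering threshold, so the
    reciprocal-best-hit map over the filtered tables equals the returned
    ground truth (template gene -> target gene) exactly.
    """
    if not (0.0 <= retention_prob <= 1.0):
        raise ValueError("retention_prob must be in [0,1]")
    rng = np.random.default_rng(seed)
    template_genes = list(template_genes)
    target_of = {g: target_prefix + g.split("_", 1)[-1] for g in template_genes}

    def good_hit(q: str, s: str) -> HitRecord:
        ppos = float(rng.uniform(max(55.0, thresholds.min_percent_positives + 10), 95.0))
        return HitRecord(
            query_id=q,
            subject_id=s,
            percent_identity=float(rng.uniform(50.0, ppos)),
            percent_positives=ppos,
            aln_length=int(rng.integers(100, 400)),
            evalue=float(10.0 ** -rng.uniform(20, 80)),
            bitscore=float(rng.uniform(thresholds.min_bitscore + 50, 600.0)),
        )

    def noise_hit(q: str, s: str) -> HitRecord:
        mode = rng.integers(0, 3)
        ppos = float(rng.uniform(55.0, 95.0))
        evalue = float(10.0 ** -rng.uniform(20, 80))
        bitscore = float(rng.uniform(150.0, 600.0))
        if mode == 0:
            evalue = float(10.0 ** -rng.uniform(1, 9))  # fails the 1e-10 cut
        elif mode == 1:
            bitscore = float(rng.uniform(10.0, thresholds.min_bitscore - 1))
        else:
            ppos = float(rng.uniform(5.0, thresholds.min_percent_positives - 1))
        return HitRecord(
            query_id=q,
            subject_id=s,
            percent_identity=float(rng.uniform(max(0.0, ppos - 30.0), ppos)),
            percent_positives=ppos,
            aln_length=int(rng.integers(50, 400)),
            evalue=evalue,
            bitscore=bitscore,
        )

    truth: dict[str, str] = {}
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    for g in template_genes:
        if rng.random() < retention_prob:
            t = target_of[g]
            truth[g] = t
            hits_ab.append(good_hit(g, t))
            hits_ba.append(good_hit(t, g))
    all_targets = [target_of[g] for g in template_genes]
    for _ in range(noise_hits):
        q = template_genes[int(rng.integers(0, len(template_genes)))]
        s = all_targets[int(rng.integers(0, len(all_targets)))]
        hits_ab.append(noise_hit(q, s))
        hits_ba.append(noise_hit(s, q))
    return hits_ab, hits_ba, truth


def write_hit_table(hits: list[HitRecord], path: Union[str, Path]) -> None:
    """Write hits in the 7-column with-positives tabular dialect."""
    lines = [
        f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t{h.percent_positives:.1f}"
        f"\t{h.aln_length}\t{h.evalue:.3e}\t{h.bitscore:.1f}"
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# strain panels


@dataclass
class GroupSpec:
    """One host group: label, size, and per-pathway presence probabilities."""

    label: str
    n_strains: int
    pathway_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        for p, prob in self.pathway_probs.items():
            if p not in PATHWAYS:
                raise ValueError(f"unknown pathway {p!r}")
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"probability for {p!r} out of [0,1]")


def _default_groups() -> list[GroupSpec]:
    """The study conditions: 16 herbivore, 15 omnivore and 4 sourdough
    strains; every sourdough strain lacks the histamine and 1,3-propanediol
    pathways; the 1-propanol route is absent in all strains."""
    carb = {p: 1.0 for p in ("EMP", "PK", "lactate", "acetate", "ethanol")}
    base = dict(carb, folate=1.0, cobalamin=1.0, propanol=0.0)
    return [
        GroupSpec("herbivore", 16, dict(base, histamine=0.9, glycerol_3HPA_PDO=0.9)),
        GroupSpec("omnivore", 15, dict(base, histamine=0.45, glycerol_3HPA_PDO=0.8)),
        GroupSpec("sourdough", 4, dict(base, histamine=0.0, glycerol_3HPA_PDO=0.0)),
    ]


@dataclass
class PanelSpec:
    """A host-group strain panel specification."""

    groups: list[GroupSpec] = field(default_factory=_default_groups)
    auxotrophy_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auxotrophy_prob <= 1.0):
            raise ValueError("auxotrophy_prob must be in [0,1]")


@dataclass
class StrainGroundTruth:
    """Planted properties of one generated strain."""

    strain_id: str
    group: str
    pathways: dict[str, bool]
    auxotrophies: list[str]
    capabilities: dict[str, bool]  # product name -> can secrete


def make_strain_panel(
    spec: Optional[PanelSpec] = None,
    template: Optional[Model] = None,
    template_truth: Optional[TemplateGroundTruth] = None,
) -> tuple[StrainPanel, list[StrainGroundTruth]]:
    """Generate a strain panel by subsetting the template's pathway modules.

    Each strain samples its pathway flags from its group's probabilities
    (acetate/ethanol are forced off without PK; PK is forced on if both
    glycolytic branches sample off) and its auxotrophies per amino acid.
    Capability ground truth follows from the flags by construction.
    """
    spec = spec or PanelSpec()
    if template is None or template_truth is None:
        template, template_truth = make_template_network(NetworkSpec(seed=spec.seed))
    rng = np.random.default_rng(spec.seed)
    members: list[tuple[str, Model, str]] = []
    truths: list[StrainGroundTruth] = []
    for group in spec.groups:
        prefix = group.label[:1].upper()
        for i in range(group.n_strains):
            sid = f"{prefix}{i + 1:02d}"
            flags = {
                p: bool(rng.random() < group.pathway_probs.get(p, 1.0)) for p in PATHWAYS
            }
            if not (flags["EMP"] or flags["PK"]):
                flags["PK"] = True  # the dominant branch in this clade
            if not flags["PK"]:
                flags["acetate"] = False
                flags["ethanol"] = False
            template_aux = set(template_truth.auxotrophies)
            auxotrophies = sorted(
                set(
                    aa
                    for aa in AMINO_ACIDS
                    if aa in template_aux or rng.random() < spec.auxotrophy_prob
                )
            )
            strain = _subset_strain(template, template_truth, sid, flags, auxotrophies)
            caps = {
                prod: flags[_PRODUCT_PATHWAY[prod]]
                and (flags["PK"] if prod in _NEEDS_PK else True)
                for prod in PRODUCTS
            }
            members.append((sid, strain, group.label))
            truths.append(
                StrainGroundTruth(
                    strain_id=sid,
                    group=group.label,
                    pathways=flags,
                    auxotrophies=auxotrophies,
                    capabilities=caps,
                )
            )
    return StrainPanel(members), truths


def _subset_strain(
    template: Model,
    truth: TemplateGroundTruth,
    strain_id: str,
    flags: dict[str, bool],
    auxotrophies: list[str],
) -> Model:
    drop: set[str] = set()
    for pathway, keep in flags.items():
        if not keep:
            drop |= set(truth.pathway_reactions.get(pathway, []))
    for aa in auxotrophies:
        drop.add(f"SYNTH_{aa}")
    strain = Model(id=strain_id)
    kept = [r for r in template.reactions if r.id not in drop]
    used_mets = {m for r in kept for m in r.stoichiometry}
    for met in template.metabolites:
        if met.id in used_mets:
            strain.add_metabolite(met.copy())
    for r in kept:
        strain.add_reaction(r.copy())
    strain.biomass_reaction_id = template.biomass_reaction_id
    strain.objective_reaction_id = template.objective_reaction_id
    strain.validate()
    return strain


# ---------------------------------------------------------------------------
# serialization helpers (CLI / pipelines)


def panel_ground_truth_json(truths: list[StrainGroundTruth]) -> str:
    return json.dumps(
        [
            {
                "strain_id": t.strain_id,
                "group": t.group,
                "pathways": t.pathways,
                "auxotrophies": t.auxotrophies,
                "capabilities": t.capabilities,
            }
            for t in truths
        ],
        indent=1,
    )


def capability_matrix(panel: StrainPanel, medium: Optional[MediumSpec] = None) -> dict[str, dict[str, bool]]:
    """Run the secretion-capability screen for the eight products on every
    panel member; returns strain id -> product -> capability."""
    medium = medium or capability_medium()
    out: dict[str, dict[str, bool]] = {}
    for sid, model, _ in panel.members:
        # restrict the medium to metabolites the strain can actually exchange
        # (a strain without the glycerol pathway has no glycerol exchange)
        usable = MediumSpec(
            name=medium.name,
            uptake_rates={
                m: r for m, r in medium.uptake_rates.items() if model.exchange_for(m) is not None
            },
        )
        row: dict[str, bool] = {}
        for prod in PRODUCTS:
            met = PRODUCT_METABOLITES[prod]
            if not model.has_metabolite(met):
                row[prod] = False
                continue
            capable, _rate = production_capability(model, met, usable)
            row[prod] = capable
        out[sid] = row
    return out
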