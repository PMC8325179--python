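"""End-to-end pipeline orchestration: reconstruct -> gapfill -> simulate -> pancore.

The three entry points mirror the analyses a strain-panel study runs:

* :func:`run_reconstruct` — orthology, draft building, priority-ordered
  template integration, exchange/transport addition, biomass adoption with
  GC-derived DNA coefficients, gap-filling, validation and a
  model-characteristics report;
* :func:`run_phenotypes` — growth (with and without EMP caps), the
  20-amino-acid omission screen and the eight-product capability screen;
* :func:`run_panel` — group summaries, core/pan models, element
  classification and the capability-by-group table.

Every run writes a frozen copy of its resolved configuration so results are
reproducible from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import io as model_io
from .errors import LimogemError
from .gapfill import GapfillProblem, apply_gapfill, find_gapfill_set
from .media import AMINO_ACIDS, MediumSpec, read_medium, reference_medium
from .model import Model, model_stats
from .orthology import ThresholdSet, bidirectional_best_hits, parse_hit_table
from .pancore import StrainPanel, classify_elements, core_model, group_summary, pan_model
from .reconstruct import (
    add_exchanges_and_transport,
    build_draft,
    dna_biomass_coefficients,
    integrate_template,
)
from .simulate import PathwayCap, growth_with_cap, omit_nutrient_screen, production_capability
from .synth import PRODUCT_METABOLITES, PRODUCTS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_reconstruct", "run_phenotypes", "run_panel", "read_group_table"]


@dataclass
class TemplateConfig:
    model_path: str
    hits_forward: str  # template -> target hit table
    hits_reverse: str  # target -> template hit table


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (YAML-friendly)."""

    templates: list[TemplateConfig] = field(default_factory=list)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    medium_path: Optional[str] = None
    gc_content: float = 0.39
    dna_mass_fraction: float = 0.031
    cap_reactions: tuple[str, ...] = ()
    cap_flux: Optional[float] = None
    products: tuple[str, ...] = PRODUCTS
    min_growth: float = 1e-6
    output_dir: str = "limogem_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        thr = doc.get("thresholds", {})
        return cls(
            templates=[TemplateConfig(**t) for t in doc.get("templates", [])],
            thresholds=ThresholdSet(
                max_evalue=float(thr.get("max_evalue", 1e-10)),
                min_bitscore=float(thr.get("min_bitscore", 100.0)),
                min_percent_positives=float(thr.get("min_percent_positives", 45.0)),
            ),
            medium_path=doc.get("medium"),
            gc_content=float(doc.get("gc_content", 0.39)),
            dna_mass_fraction=float(doc.get("dna_mass_fraction", 0.031)),
            cap_reactions=tuple(doc.get("cap_reactions", ())),
            cap_flux=doc.get("cap_flux"),
            products=tuple(doc.get("products", PRODUCTS)),
            min_growth=float(doc.get("min_growth", 1e-6)),
            output_dir=str(doc.get("output_dir", "limogem_out")),
            seed=int(doc.get("seed", 0)),
            log_level=str(doc.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        return {
            "templates": [vars(t) for t in self.templates],
            "thresholds": vars(self.thresholds),
            "medium": self.medium_path,
            "gc_content": self.gc_content,
            "dna_mass_fraction": self.dna_mass_fraction,
            "cap_reactions": list(self.cap_reactions),
            "cap_flux": self.cap_flux,
            "products": list(self.products),
            "min_growth": self.min_growth,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def freeze(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_medium(config: PipelineConfig) -> MediumSpec:
    if config.medium_path:
        return read_medium(config.medium_path)
    return reference_medium()


def run_reconstruct(config: PipelineConfig, target_id: str = "reconstruction") -> Model:
    """Run the full reconstruction pipeline; writes model + report to the
    configured output directory and returns the final model."""
    outdir = Path(config.output_dir)
    config.freeze(outdir)
    if not config.templates:
        raise LimogemError("reconstruction needs at least one template")

    stage = "orthology"
    try:
        templates: list[tuple[Model, dict[str, str]]] = []
        for tc in config.templates:
            template = model_io.read_model(tc.model_path, _dialect_of(tc.model_path))
            hits_ab = parse_hit_table(tc.hits_forward)
            hits_ba = parse_hit_table(tc.hits_reverse)
            pairs = bidirectional_best_hits(hits_ab, hits_ba, config.thresholds)
            # gene_a is the template gene; build_draft maps target -> template
            ortholog_map = {p.gene_b: p.gene_a for p in pairs}
            logger.info(
                "orthology %s: %d/%d forward hits kept, %d BBH pairs",
                template.id,
                len(hits_ab),
                len(hits_ab),
                len(pairs),
            )
            templates.append((template, ortholog_map))

        stage = "draft"
        primary, primary_map = templates[0]
        model = build_draft(primary, primary_map, draft_id=target_id)
        logger.info("draft: %d reactions from primary template %s", len(model.reactions), primary.id)

        stage = "integration"
        for template, ortholog_map in templates[1:]:
            model = integrate_template(model, template, ortholog_map)

        stage = "exchanges"
        medium = _load_medium(config)
        model = add_exchanges_and_transport(model, medium, templates)

        stage = "biomass"
        model = _adopt_biomass(model, primary, config)

        stage = "gapfill"
        if model.biomass_reaction_id is not None:
            problem = GapfillProblem(
                base=model, pool=primary, objective_id=model.biomass_reaction_id,
                min_growth=config.min_growth,
            )
            solution = find_gapfill_set(problem)
            logger.info("gapfill: %d reactions added", len(solution.added_reaction_ids))
            model = apply_gapfill(model, solution, primary)

        stage = "validation"
        model.validate()
        model_io.write_model(model, outdir / f"{target_id}.xml")
        model_io.write_model(model, outdir / f"{target_id}.json", dialect="json")
        _write_stats(model, outdir / f"{target_id}.stats.tsv")
        return model
    except LimogemError as exc:
        failed = outdir / "failed"
        failed.mkdir(parents=True, exist_ok=True)
        (failed / "stage.txt").write_text(f"{stage}\n{exc}\n")
        raise LimogemError(f"[{stage}] {exc}") from exc


def _dialect_of(path: Union[str, Path]) -> str:
    return "json" if str(path).endswith(".json") else "sbml_fbc"


def _adopt_biomass(model: Model, primary: Model, config: PipelineConfig) -> Model:
    """Copy the primary template's biomass reaction, replacing its dNMP
    terms with GC-derived coefficients; also carry the biomass drain."""
    if primary.biomass_reaction_id is None:
        return model
    out = model.copy()
    biomass = primary.reaction(primary.biomass_reaction_id).copy()
    dna = dna_biomass_coefficients(config.gc_content, config.dna_mass_fraction)
    for n, coeff in dna.coefficients.items():
        met = f"{n}_c"
        if met in biomass.stoichiometry:
            biomass.stoichiometry[met] = -coeff
    from .reconstruct import _merge_metabolite

    for met_id in biomass.stoichiometry:
        _merge_metabolite(out, primary.metabolite(met_id))
    if not out.has_reaction(biomass.id):
        out.add_reaction(biomass)
    out.biomass_reaction_id = biomass.id
    out.objective_reaction_id = biomass.id
    # carry drains for the biomass pseudo-metabolite
    for rxn in primary.reactions:
        if (
            not out.has_reaction(rxn.id)
            and len(rxn.stoichiometry) == 1
            and next(iter(rxn.stoichiometry)) in biomass.stoichiometry
            and biomass.stoichiometry[next(iter(rxn.stoichiometry))] > 0
        ):
            out.add_reaction(rxn.copy())
    return out


def _write_stats(model: Model, path: Path) -> None:
    stats = model_stats(model)
    lines = ["category\tvalue"]
    for label, value in stats.to_rows():
        lines.append(f"{label}\t{value}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


def run_phenotypes(config: PipelineConfig, model: Model) -> dict:
    """Growth verdicts, omission screen and capability vector; TSVs are
    written to the output directory and the tables returned as dicts."""
    outdir = Path(config.output_dir)
    config.freeze(outdir)
    medium = _load_medium(config)

    growth = growth_with_cap(model, medium)
    capped = None
    if config.cap_reactions and config.cap_flux is not None:
        cap = PathwayCap(tuple(config.cap_reactions), float(config.cap_flux))
        capped = growth_with_cap(model, medium, cap)

    nutrients = [f"{aa}_e" for aa in AMINO_ACIDS if f"{aa}_e" in medium.uptake_rates]
    omission = omit_nutrient_screen(model, medium, nutrients)

    capability: dict[str, bool] = {}
    for prod in config.products:
        met = PRODUCT_METABOLITES.get(prod, prod)
        if not model.has_metabolite(met):
            capability[prod] = False
            continue
        usable = MediumSpec(
            name=medium.name,
            uptake_rates={
                m: r for m, r in medium.uptake_rates.items() if model.exchange_for(m) is not None
            },
        )
        capable, _ = production_capability(model, met, usable)
        capability[prod] = capable

    lines = ["condition\tgrows\trate"]
    lines.append(f"growth\t{int(growth.grows)}\t{growth.rate:.6g}")
    if capped is not None:
        lines.append(f"growth_capped\t{int(capped.grows)}\t{capped.rate:.6g}")
    for nutrient in nutrients:
        v = omission[nutrient]
        lines.append(f"omit:{nutrient}\t{int(v.grows)}\t{v.rate:.6g}")
    (outdir / "phenotypes.tsv").write_text("\n".join(lines) + "\n")

    cap_lines = ["product\tcapability"] + [
        f"{p}\t{int(capability[p])}" for p in config.products
    ]
    (outdir / "capability.tsv").write_text("\n".join(cap_lines) + "\n")

    return {
        "growth": growth,
        "growth_capped": capped,
        "omission": omission,
        "capability": capability,
    }


# ---------------------------------------------------------------------------
# panel analysis


def read_group_table(path: Union[str, Path]) -> dict[str, str]:
    """Read a strain -> group TSV (two columns, optional header)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("strain\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise LimogemError(f"{path}: group table rows need 2 tab-separated columns")
        mapping[fields[0]] = fields[1]
    return mapping


def load_panel(models_dir: Union[str, Path], groups_path: Union[str, Path]) -> StrainPanel:
    """Assemble a panel from a directory of model files plus a group TSV."""
    groups = read_group_table(groups_path)
    members = []
    for sid in sorted(groups):
        candidates = [
            p
            for ext in (".xml", ".sbml", ".json")
            for p in [Path(models_dir) / f"{sid}{ext}"]
            if p.exists()
        ]
        if not candidates:
            raise LimogemError(f"no model file for strain {sid!r} under {models_dir}")
        model = model_io.read_model(candidates[0], _dialect_of(candidates[0]))
        members.append((sid, model, groups[sid]))
    return StrainPanel(members)


def run_panel(
    panel: StrainPanel,
    output_dir: Union[str, Path],
    identity: str = "signature",
    kinds: Sequence[str] = ("gene", "reaction", "metabolite"),
) -> dict:
    """Group summaries, overall core/pan models, classification tables and
    the capability-by-group table."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary = group_summary(panel, identity=identity)
    lines = [
        "group\tn_strains\tkind\tmean\tsd\tcore\tpan\tcore_pan_pct"
    ]
    for g in panel.groups:
        for kind in ("reaction", "metabolite", "gene"):
            mean, sd = summary.sizes[g][kind]
            lines.append(
                f"{g}\t{summary.n_strains[g]}\t{kind}\t{mean:.1f}\t{sd:.1f}"
                f"\t{summary.core[g][kind]}\t{summary.pan[g][kind]}"
                f"\t{summary.core_pan_pct[g][kind]:.1f}"
            )
    (outdir / "group_summary.tsv").write_text("\n".join(lines) + "\n")

    core = core_model(panel.models, identity=identity)
    pan = pan_model(panel.models, identity=identity)
    model_io.write_model(core, outdir / "core.xml")
    model_io.write_model(pan, outdir / "pan.xml")

    classifications = {}
    cls_lines = ["kind\tstatus\tcount\tpct_of_union"]
    for kind in kinds:
        cls = classify_elements(panel, kind, identity=identity)
        classifications[kind] = cls
        pct = cls.percentages()
        cls_lines.append(f"{kind}\tcommon\t{len(cls.common)}\t{pct['common']:.1f}")
        cls_lines.append(f"{kind}\tdispensable\t{len(cls.dispensable)}\t{pct['dispensable']:.1f}")
        cls_lines.append(f"{kind}\tspecific\t{len(cls.specific_all)}\t{pct['specific']:.1f}")
    (outdir / "classification.tsv").write_text("\n".join(cls_lines) + "\n")

    from .synth import capability_matrix

    caps = capability_matrix(panel)
    by_group: dict[str, dict[str, float]] = {}
    for g in panel.groups:
        sids = [sid for sid, _, grp in panel.members if grp == g]
        by_group[g] = {
            prod: 100.0 * sum(caps[sid][prod] for sid in sids) / len(sids)
            for prod in PRODUCTS
        }
    cap_lines = ["group\t" + "\t".join(PRODUCTS)]
    for g in panel.groups:
        cap_lines.append(g + "\t" + "\t".join(f"{by_group[g][p]:.1f}" for p in PRODUCTS))
    (outdir / "capability_by_group.tsv").write_text("\n".join(cap_lines) + "\n")

    (outdir / "panel_summary.json").write_text(
        json.dumps(
            {
                "core_reactions": len(core.reactions),
                "core_metabolites": len(core.metabolites),
                "pan_reactions": len(pan.reactions),
                "pan_metabolites": len(pan.metabolites),
            },
            indent=1,
        )
    )
    return {
        "summary": summary,
        "core": core,
        "pan": pan,
        "classifications": classifications,
        "capability_by_group": by_group,
    }
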