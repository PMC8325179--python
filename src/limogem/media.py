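"""Growth-medium definitions.

A medium is a named map from extracellular metabolite id to maximum uptake
rate (mmol/gDW/h).  Concentrations (e.g. "111 mM glucose" in a chemically
defined medium) are metadata only: FBA operates on rates, so flux bounds
always come from measured or assumed uptake rates, never concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .errors import FormatError

__all__ = ["MediumSpec", "read_medium", "write_medium", "AMINO_ACIDS", "reference_medium"]

#: Three-letter codes for the 20 proteinogenic amino acids.
AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: Default glucose uptake rate (mmol/gDW/h) for growth simulations.
GLUCOSE_UPTAKE = 25.0

#: Default amino-acid uptake rate (mmol/gDW/h); a permissive supply so that
#: auxotrophy verdicts are decided by pathway presence, not rate limits.
AMINO_ACID_UPTAKE = 5.0


@dataclass
class MediumSpec:
    """A named growth condition: metabolite id -> max uptake rate."""

    name: str
    uptake_rates: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, rate in self.uptake_rates.items():
            if rate < 0:
                raise ValueError(f"negative uptake rate for {met!r}: {rate}")

    def with_rate(self, met_id: str, rate: float) -> "MediumSpec":
        rates = dict(self.uptake_rates)
        rates[met_id] = rate
        return MediumSpec(name=self.name, uptake_rates=rates, metadata=dict(self.metadata))

    def without(self, met_id: str) -> "MediumSpec":
        rates = {k: v for k, v in self.uptake_rates.items() if k != met_id}
        return MediumSpec(name=self.name, uptake_rates=rates, metadata=dict(self.metadata))


def reference_medium(glycerol: bool = False) -> MediumSpec:
    """Chemically defined reference medium: glucose as sole carbon source at
    25 mmol/gDW/h plus the 20 amino acids (optionally glycerol)."""
    rates = {"glc_e": GLUCOSE_UPTAKE}
    for aa in AMINO_ACIDS:
        rates[f"{aa}_e"] = AMINO_ACID_UPTAKE
    if glycerol:
        rates["glyc_e"] = GLUCOSE_UPTAKE
    return MediumSpec(
        name="cdm_glc" + ("_glyc" if glycerol else ""),
        uptake_rates=rates,
        metadata={"glucose_concentration_mM": 111},
    )


def read_medium(path: Union[str, Path]) -> MediumSpec:
    """Read a medium from YAML (``name`` + ``uptake_rates``) or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict) or "uptake_rates" not in doc:
            raise FormatError(f"{path}: medium YAML needs an 'uptake_rates' mapping")
        return MediumSpec(
            name=str(doc.get("name", path.stem)),
            uptake_rates={str(k): float(v) for k, v in doc["uptake_rates"].items()},
            metadata=dict(doc.get("metadata", {})),
        )
    rates: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'metabolite<TAB>rate'")
        try:
            rates[fields[0]] = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return MediumSpec(name=path.stem, uptake_rates=rates)


def write_medium(medium: MediumSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = {
        "name": medium.name,
        "uptake_rates": dict(sorted(medium.uptake_rates.items())),
        "metadata": medium.metadata,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
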