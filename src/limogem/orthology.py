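"""Bidirectional best hits (BBH) orthology from protein-alignment hit tables.

Hit tables are BLASTP-style tabular files.  The filtering thresholds follow
the reciprocal-best-hit protocol used for lactic acid bacteria proteome
comparison: E-value <= 1e-10, bit score >= 100 and percentage of positive
scoring matches >= 45, all inclusive.

Standard 12-column BLAST tabular output (``-outfmt 6``) does not include
the positives percentage; producing the required table needs
``-outfmt "6 qseqid sseqid pident ppos length evalue bitscore"``.  The
``blast_tab_std`` dialect therefore exists only to fail loudly with an
explanation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .errors import ConfigurationError, FormatError

__all__ = [
    "HitRecord",
    "ThresholdSet",
    "OrthologPair",
    "parse_hit_table",
    "filter_hits",
    "best_hits",
    "bidirectional_best_hits",
    "write_ortholog_map",
    "read_ortholog_map",
]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein-alignment hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    percent_positives: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if not (0.0 <= self.percent_positives <= 100.0):
            raise ValueError(f"percent_positives out of [0,100]: {self.percent_positives}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore: {self.bitscore}")


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusive hit-filtering thresholds (defaults: 1e-10, 100, 45%)."""

    max_evalue: float = 1e-10
    min_bitscore: float = 100.0
    min_percent_positives: float = 45.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_percent_positives <= 100.0):
            raise ValueError("min_percent_positives must be in [0,100]")

    def accepts(self, hit: HitRecord) -> bool:
        return (
            hit.evalue <= self.max_evalue
            and hit.bitscore >= self.min_bitscore
            and hit.percent_positives >= self.min_percent_positives
        )


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best-hit gene pair with its supporting alignments."""

    gene_a: str
    gene_b: str
    forward_hit: HitRecord
    reverse_hit: HitRecord


#: column order of the custom 7-column dialect carrying percent positives
_WITH_POSITIVES_COLS = 7


def parse_hit_table(
    path: Union[str, Path], dialect: str = "blast_tab_with_positives"
) -> list[HitRecord]:
    """Parse a tab/whitespace-delimited hit table into :class:`HitRecord` s.

    ``blast_tab_with_positives`` columns: query, subject, pident, ppos,
    length, evalue, bitscore.  Blank lines and ``#`` comments are skipped;
    malformed rows raise with their line number.
    """
    if dialect == "blast_tab_std":
        raise ConfigurationError(
            "standard 12-column BLAST tabular output lacks the percent-positives "
            "column required for filtering; regenerate with "
            '-outfmt "6 qseqid sseqid pident ppos length evalue bitscore" '
            "and use dialect 'blast_tab_with_positives'"
        )
    if dialect != "blast_tab_with_positives":
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    path = Path(path)
    records: list[HitRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != _WITH_POSITIVES_COLS:
            raise FormatError(
                f"{path}:{lineno}: expected {_WITH_POSITIVES_COLS} columns, got {len(fields)}"
            )
        try:
            records.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    percent_positives=float(fields[3]),
                    aln_length=int(fields[4]),
                    evalue=float(fields[5]),
                    bitscore=float(fields[6]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def filter_hits(hits: Iterable[HitRecord], thresholds: ThresholdSet = ThresholdSet()) -> list[HitRecord]:
    """Keep hits passing all three thresholds (inclusive comparisons)."""
    return [h for h in hits if thresholds.accepts(h)]


def best_hits(hits: Iterable[HitRecord], discard_self: bool = True) -> dict[str, str]:
    """Per query, the subject with the highest bitscore.

    Ties break by lower E-value, then lexicographically smallest subject id.
    Self-hits (query == subject) are discarded by default since BBH compares
    distinct genomes.
    """
    best: dict[str, HitRecord] = {}
    for hit in hits:
        if discard_self and hit.query_id == hit.subject_id:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return {q: h.subject_id for q, h in best.items()}


def _hit_rank(hit: HitRecord) -> tuple:
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def bidirectional_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    thresholds: ThresholdSet = ThresholdSet(),
) -> list[OrthologPair]:
    """Reciprocal best hits between genome A and genome B.

    A pair (a, b) is emitted iff b is a's best surviving hit in the A->B
    table and a is b's best in the B->A table.  Output is sorted by gene_a.
    """
    kept_ab = filter_hits(hits_ab, thresholds)
    kept_ba = filter_hits(hits_ba, thresholds)
    fwd = best_hits(kept_ab)
    rev = best_hits(kept_ba)
    fwd_hit = {(h.query_id, h.subject_id): h for h in kept_ab}
    rev_hit = {(h.query_id, h.subject_id): h for h in kept_ba}
    pairs: list[OrthologPair] = []
    for a, b in fwd.items():
        if rev.get(b) == a:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=b,
                    forward_hit=fwd_hit[(a, b)],
                    reverse_hit=rev_hit[(b, a)],
                )
            )
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def write_ortholog_map(pairs: Iterable[OrthologPair], path: Union[str, Path]) -> None:
    """Emit an ortholog map as two-column TSV (gene_a, gene_b)."""
    lines = [f"{p.gene_a}\t{p.gene_b}" for p in pairs]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_ortholog_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column TSV ortholog map into a gene_a -> gene_b dict."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        mapping[fields[0]] = fields[1]
    return mapping
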