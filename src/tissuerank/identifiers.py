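"""Gene identifier resolution, ortholog mapping and the gene model.

Candidate genes arrive as HGNC-approved symbols, common aliases, or
Ensembl/Entrez/RefSeq accessions, in any mixture. Resolution walks a fixed
precedence ladder (approved symbol > Ensembl > Entrez > RefSeq > alias);
symbols and aliases match case-insensitively, accessions case-sensitively
with a trailing ``.N`` version suffix stripped. When several genes match
the same token, the ambiguity can optionally be broken in favour of the
unique match that has expression data; beyond that the tool never guesses.

Mouse evidence is transferred to human candidates through a one-to-one
ortholog table; rows participating in one-to-many relationships are dropped
with a warning, because scoring needs an unambiguous expression profile per
candidate.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import InputFormatError
from .expression import Species

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_version(accession: str) -> str:
    """Remove a trailing '.N' version suffix from an accession."""
    return _VERSION_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifiers, aliases and genomic placement (1-based inclusive)."""

    canonical_id: str
    approved_symbol: str
    species: Species
    chromosome: str
    span_start: int
    span_end: int
    aliases: frozenset[str] = frozenset()
    ensembl_id: Optional[str] = None
    entrez_id: Optional[str] = None
    refseq_id: Optional[str] = None
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(self, "aliases", frozenset(self.aliases))
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.span_start > self.span_end or self.span_start < 1:
            raise ValueError(
                f"gene {self.canonical_id!r}: invalid span "
                f"{self.span_start}-{self.span_end}"
            )
        for start, end in self.exons:
            if start > end or start < self.span_start or end > self.span_end:
                raise ValueError(
                    f"gene {self.canonical_id!r}: exon {start}-{end} outside span "
                    f"{self.span_start}-{self.span_end}"
                )


class ResolutionStatus(str, Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    UNRESOLVED = "unresolved"


@dataclass
class Resolution:
    """Outcome of resolving one input token against the gene registry."""

    input_token: str
    status: ResolutionStatus
    matches: list[str] = field(default_factory=list)
    chosen: Optional[str] = None
    rule_applied: str = ""

    def __post_init__(self) -> None:
        self.status = ResolutionStatus(self.status)
        if self.status is ResolutionStatus.RESOLVED and self.chosen is None:
            raise ValueError(f"{self.input_token!r}: resolved without a chosen gene")
        if self.status is ResolutionStatus.UNRESOLVED and self.matches:
            raise ValueError(f"{self.input_token!r}: unresolved but matches present")


class GeneRegistry:
    """Indexed gene records for fast, deterministic identifier resolution.

    Enforces uniqueness of canonical ids and approved symbols per species.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        if not self.records:
            raise ValueError("empty gene registry")
        self._by_canonical: dict[str, GeneRecord] = {}
        self._by_symbol: dict[str, list[GeneRecord]] = {}
        self._by_alias: dict[str, list[GeneRecord]] = {}
        self._by_ensembl: dict[str, list[GeneRecord]] = {}
        self._by_entrez: dict[str, list[GeneRecord]] = {}
        self._by_refseq: dict[str, list[GeneRecord]] = {}
        seen_symbol: set[tuple[Species, str]] = set()
        for rec in self.records:
            if rec.canonical_id in self._by_canonical:
                other = self._by_canonical[rec.canonical_id]
                if other.species == rec.species:
                    raise ValueError(f"duplicate canonical id {rec.canonical_id!r}")
            key = (rec.species, rec.approved_symbol.lower())
            if key in seen_symbol:
                raise ValueError(
                    f"duplicate approved symbol {rec.approved_symbol!r} "
                    f"for species {rec.species.value}"
                )
            seen_symbol.add(key)
            self._by_canonical[rec.canonical_id] = rec
            self._by_symbol.setdefault(rec.approved_symbol.lower(), []).append(rec)
            for alias in rec.aliases:
                self._by_alias.setdefault(alias.lower(), []).append(rec)
            if rec.ensembl_id:
                self._by_ensembl.setdefault(strip_version(rec.ensembl_id), []).append(rec)
            if rec.entrez_id:
                self._by_entrez.setdefault(rec.entrez_id, []).append(rec)
            if rec.refseq_id:
                self._by_refseq.setdefault(strip_version(rec.refseq_id), []).append(rec)

    def get(self, canonical_id: str) -> Optional[GeneRecord]:
        return self._by_canonical.get(canonical_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # ladder lookups, in precedence order
    def _ladder(self, token: str) -> list[tuple[str, list[GeneRecord]]]:
        acc = strip_version(token)
        return [
            ("approved_symbol", self._by_symbol.get(token.lower(), [])),
            ("ensembl_id", self._by_ensembl.get(acc, [])),
            ("entrez_id", self._by_entrez.get(token, [])),
            ("refseq_id", self._by_refseq.get(acc, [])),
            ("alias", self._by_alias.get(token.lower(), [])),
        ]


def resolve_identifier(
    token: str,
    registry: GeneRegistry | Iterable[GeneRecord],
    resolve_ambiguous: bool = False,
    expression_gene_ids: frozenset[str] | set[str] = frozenset(),
) -> Resolution:
    """Resolve one token to a canonical gene id.

    The first precedence level with any match determines the candidate set.
    A unique match resolves directly. With several matches and
    ``resolve_ambiguous`` set, the single match backed by expression data
    wins; otherwise the token is reported ambiguous with all matches listed.
    """
    if not isinstance(registry, GeneRegistry):
        registry = GeneRegistry(registry)
    for rule, hits in registry._ladder(token):
        if not hits:
            continue
        matches = sorted({r.canonical_id for r in hits})
        if len(matches) == 1:
            return Resolution(token, ResolutionStatus.RESOLVED, matches, matches[0], rule)
        if resolve_ambiguous:
            with_data = [m for m in matches if m in expression_gene_ids]
            if len(with_data) == 1:
                return Resolution(
                    token,
                    ResolutionStatus.RESOLVED,
                    matches,
                    with_data[0],
                    f"{rule}+expression_presence",
                )
        return Resolution(token, ResolutionStatus.AMBIGUOUS, matches, None, rule)
    return Resolution(token, ResolutionStatus.UNRESOLVED, [], None, "no_match")


@dataclass(frozen=True)
class OrthologPair:
    human_canonical_id: str
    mouse_canonical_id: str


class OrthologDirection(str, Enum):
    HUMAN_TO_MOUSE = "human_to_mouse"
    MOUSE_TO_HUMAN = "mouse_to_human"


def map_ortholog(
    canonical_id: str,
    direction: OrthologDirection | str,
    pairs: Sequence[OrthologPair],
) -> Optional[str]:
    """Look up a gene's one-to-one ortholog partner, or None if unpaired."""
    direction = OrthologDirection(direction)
    if direction is OrthologDirection.HUMAN_TO_MOUSE:
        table = {p.human_canonical_id: p.mouse_canonical_id for p in pairs}
    else:
        table = {p.mouse_canonical_id: p.human_canonical_id for p in pairs}
    return table.get(canonical_id)


# --------------------------------------------------------------------------
# Tabular IO
# --------------------------------------------------------------------------

_GENE_COLUMNS = (
    "canonical_id", "species", "approved_symbol", "aliases", "ensembl_id",
    "entrez_id", "refseq_id", "chromosome", "span_start", "span_end", "exons",
)
_ORTHOLOG_COLUMNS = ("human_canonical_id", "mouse_canonical_id")


def _parse_exons(text: str, lineno: int) -> tuple[tuple[int, int], ...]:
    if not text:
        return ()
    exons = []
    for part in text.split(","):
        try:
            start_s, end_s = part.split("-")
            exons.append((int(start_s), int(end_s)))
        except ValueError:
            raise InputFormatError(f"malformed exon {part!r}", lineno) from None
    return tuple(exons)


def read_gene_model(path: str | Path) -> list[GeneRecord]:
    """Read a gene model TSV; validates coordinates and symbol uniqueness."""
    path = Path(path)
    records: list[GeneRecord] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _GENE_COLUMNS:
                    raise InputFormatError(
                        f"bad header {fields!r}; expected {list(_GENE_COLUMNS)}", lineno
                    )
                header_seen = True
                continue
            if len(fields) != len(_GENE_COLUMNS):
                raise InputFormatError(
                    f"expected {len(_GENE_COLUMNS)} columns, got {len(fields)}", lineno
                )
            (canonical, species, symbol, aliases, ensembl, entrez, refseq,
             chrom, start_s, end_s, exons_s) = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise InputFormatError(
                    f"unparseable coordinates {start_s!r}/{end_s!r}", lineno
                ) from None
            try:
                records.append(
                    GeneRecord(
                        canonical_id=canonical,
                        approved_symbol=symbol,
                        species=Species(species),
                        chromosome=chrom,
                        span_start=start,
                        span_end=end,
                        aliases=frozenset(a for a in aliases.split("|") if a),
                        ensembl_id=ensembl or None,
                        entrez_id=entrez or None,
                        refseq_id=refseq or None,
                        exons=_parse_exons(exons_s, lineno),
                    )
                )
            except ValueError as exc:
                raise InputFormatError(str(exc), lineno) from None
    if not header_seen:
        raise InputFormatError(f"{path}: empty gene model (no header)")
    GeneRegistry(records)  # enforce uniqueness invariants
    return records


def write_gene_model(records: Iterable[GeneRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for rec in sorted(records, key=lambda r: (r.species.value, r.canonical_id)):
            fh.write(
                "\t".join(
                    (
                        rec.canonical_id,
                        rec.species.value,
                        rec.approved_symbol,
                        "|".join(sorted(rec.aliases)),
                        rec.ensembl_id or "",
                        rec.entrez_id or "",
                        rec.refseq_id or "",
                        rec.chromosome,
                        str(rec.span_start),
                        str(rec.span_end),
                        ",".join(f"{s}-{e}" for s, e in rec.exons),
                    )
                )
                + "\n"
            )


def read_ortholog_table(path: str | Path) -> list[OrthologPair]:
    """Read an ortholog TSV, keeping only strictly one-to-one pairs.

    Rows whose human or mouse gene appears more than once are dropped with
    a logged warning.
    """
    path = Path(path)
    raw_pairs: list[OrthologPair] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _ORTHOLOG_COLUMNS:
                    raise InputFormatError(
                        f"bad header {fields!r}; expected {list(_ORTHOLOG_COLUMNS)}", lineno
                    )
                header_seen = True
                continue
            if len(fields) != 2 or not all(fields):
                raise InputFormatError("expected 2 non-empty columns", lineno)
            raw_pairs.append(OrthologPair(fields[0], fields[1]))
    if not header_seen:
        raise InputFormatError(f"{path}: empty ortholog table (no header)")
    human_counts = Counter(p.human_canonical_id for p in raw_pairs)
    mouse_counts = Counter(p.mouse_canonical_id for p in raw_pairs)
    kept, dropped = [], []
    for p in raw_pairs:
        if human_counts[p.human_canonical_id] == 1 and mouse_counts[p.mouse_canonical_id] == 1:
            kept.append(p)
        else:
            dropped.append(p)
    if dropped:
        logger.warning(
            "dropped %d ortholog rows that are not one-to-one: %s",
            len(dropped),
            ", ".join(f"{p.human_canonical_id}~{p.mouse_canonical_id}" for p in dropped),
        )
    return kept


def write_ortholog_table(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_ORTHOLOG_COLUMNS) + "\n")
        for p in sorted(pairs, key=lambda p: p.human_canonical_id):
            fh.write(f"{p.human_canonical_id}\t{p.mouse_canonical_id}\n")
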