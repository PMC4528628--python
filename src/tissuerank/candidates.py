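"""Candidate gene input: genomic regions, pre-filtered VCFs, gene lists.

All three input forms reduce to a :class:`CandidateSet` — resolved canonical
gene ids with provenance, plus any unresolved or ambiguous tokens.
Coordinates are 1-based inclusive throughout ("chr1:100-200" strings in the
UCSC convention). Variant-to-gene assignment intersects the variant
footprint (POS plus REF length − 1) with the full gene span by default;
exon-only overlap is available as a flag. Chromosome names are compared
with a leading "chr" prefix normalized away.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

from .errors import InputFormatError
from .identifiers import GeneRecord, GeneRegistry, Resolution, ResolutionStatus, resolve_identifier

logger = logging.getLogger(__name__)

#: Default cap on VCF records, standing in for an upload size limit.
DEFAULT_VCF_RECORD_CAP = 10_000

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class GenomicRegion:
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid region {self.chromosome}:{self.start}-{self.end}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicRegion:
    """Parse a 'chr:start-end' region string (1-based inclusive)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise InputFormatError(f"unparseable region {text!r}; expected chr:start-end")
    return GenomicRegion(m.group(1), int(m.group(2)), int(m.group(3)))


@dataclass
class Candidate:
    canonical_id: str
    provenance: list[tuple[str, str]] = field(default_factory=list)

    @property
    def kinds(self) -> frozenset[str]:
        return frozenset(kind for kind, _ in self.provenance)


@dataclass
class CandidateSet:
    """Resolved candidates (unique canonical ids) plus reported ambiguities."""

    candidates: list[Candidate] = field(default_factory=list)
    ambiguities: list[Resolution] = field(default_factory=list)

    def add(self, canonical_id: str, kind: str, detail: str) -> None:
        for cand in self.candidates:
            if cand.canonical_id == canonical_id:
                if (kind, detail) not in cand.provenance:
                    cand.provenance.append((kind, detail))
                return
        self.candidates.append(Candidate(canonical_id, [(kind, detail)]))

    def gene_ids(self) -> list[str]:
        return [c.canonical_id for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    @classmethod
    def from_gene_ids(cls, gene_ids: Iterable[str], kind: str = "list_token") -> "CandidateSet":
        cs = cls()
        for g in gene_ids:
            cs.add(g, kind, g)
        return cs


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # closed-interval overlap by >= 1 base
    return a_start <= b_end and b_start <= a_end


def _sorted_hits(hits: dict[str, GeneRecord], cs: CandidateSet) -> CandidateSet:
    order = {
        rec.canonical_id: (rec.chromosome, rec.span_start, rec.canonical_id)
        for rec in hits.values()
    }
    cs.candidates.sort(key=lambda c: order[c.canonical_id])
    return cs


def genes_from_regions(
    regions: Sequence[GenomicRegion],
    gene_model: Iterable[GeneRecord],
) -> CandidateSet:
    """Genes whose span overlaps any region by at least one base.

    Output order is deterministic: (chromosome, span start, canonical id).
    Regions on chromosomes absent from the gene model are skipped with a
    warning.
    """
    records = list(gene_model)
    known = {_norm_chrom(rec.chromosome) for rec in records}
    cs = CandidateSet()
    hits: dict[str, GeneRecord] = {}
    for region in regions:
        chrom = _norm_chrom(region.chromosome)
        if chrom not in known:
            logger.warning("region %s: chromosome not in gene model; skipped", region)
            continue
        for rec in records:
            if _norm_chrom(rec.chromosome) != chrom:
                continue
            if _overlaps(rec.span_start, rec.span_end, region.start, region.end):
                cs.add(rec.canonical_id, "region", str(region))
                hits[rec.canonical_id] = rec
    return _sorted_hits(hits, cs)


def genes_from_vcf(
    path: str | Path,
    gene_model: Iterable[GeneRecord],
    max_records: int = DEFAULT_VCF_RECORD_CAP,
    exon_only: bool = False,
) -> CandidateSet:
    """Genes hit by variants of a pre-filtered VCF (v4.x; CHROM/POS/REF used).

    The variant footprint is [POS, POS + len(REF) - 1], covering deletions.
    ``exon_only`` restricts overlap to exon intervals instead of the full
    gene span. More than ``max_records`` records is an error.
    """
    records = list(gene_model)
    cs = CandidateSet()
    hits: dict[str, GeneRecord] = {}
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise InputFormatError(f"unparseable VCF {path}: {exc}") from exc
    try:
        n = 0
        for variant in vcf:
            n += 1
            if n > max_records:
                raise InputFormatError(
                    f"VCF {path} exceeds the record cap of {max_records}"
                )
            chrom = _norm_chrom(variant.CHROM)
            start = variant.POS
            end = variant.POS + max(len(variant.REF) - 1, 0)
            for rec in records:
                if _norm_chrom(rec.chromosome) != chrom:
                    continue
                if exon_only:
                    hit = any(_overlaps(s, e, start, end) for s, e in rec.exons)
                else:
                    hit = _overlaps(rec.span_start, rec.span_end, start, end)
                if hit:
                    cs.add(rec.canonical_id, "variant", f"{variant.CHROM}:{variant.POS}")
                    hits[rec.canonical_id] = rec
    finally:
        vcf.close()
    return _sorted_hits(hits, cs)


_DELIMITERS = re.compile(r"[,;\s]+")


def parse_gene_list(text: str) -> list[str]:
    """Split a delimited gene list on commas, semicolons and whitespace.

    Keeps first-seen order; de-duplicates case-insensitively, keeping the
    first form encountered.
    """
    tokens: list[str] = []
    seen: set[str] = set()
    for raw in _DELIMITERS.split(text):
        token = raw.strip()
        if not token:
            continue
        key = token.lower()
        if key not in seen:
            seen.add(key)
            tokens.append(token)
    return tokens


def candidates_from_tokens(
    tokens: Sequence[str],
    registry: GeneRegistry | Iterable[GeneRecord],
    resolve_ambiguous: bool = False,
    expression_gene_ids: frozenset[str] | set[str] = frozenset(),
    mouse_registry: GeneRegistry | Iterable[GeneRecord] | None = None,
    orthologs: Sequence["OrthologPair"] | None = None,
) -> CandidateSet:
    """Resolve gene-list tokens into a CandidateSet of human genes.

    Tokens are resolved against the (human) ``registry`` first. Tokens that
    fail there are optionally retried against ``mouse_registry``; a mouse
    hit is converted to its human ortholog (mouse symbols differ from their
    human counterparts only in case, so users may paste either). Tokens
    that stay ambiguous or unresolved — including mouse genes without a
    one-to-one ortholog — are collected under ``ambiguities`` rather than
    silently dropped.
    """
    if not isinstance(registry, GeneRegistry):
        registry = GeneRegistry(registry)
    if mouse_registry is not None and not isinstance(mouse_registry, GeneRegistry):
        mouse_registry = GeneRegistry(mouse_registry)
    mouse_to_human = (
        {p.mouse_canonical_id: p.human_canonical_id for p in orthologs}
        if orthologs is not None
        else {}
    )
    cs = CandidateSet()
    for token in tokens:
        res = resolve_identifier(token, registry, resolve_ambiguous, expression_gene_ids)
        if res.status is ResolutionStatus.RESOLVED:
            cs.add(res.chosen, "list_token", token)
            continue
        if res.status is ResolutionStatus.UNRESOLVED and mouse_registry is not None:
            mres = resolve_identifier(token, mouse_registry, resolve_ambiguous)
            if mres.status is ResolutionStatus.RESOLVED:
                human = mouse_to_human.get(mres.chosen)
                if human is not None:
                    cs.add(human, "list_token", f"{token} (mouse ortholog)")
                    continue
                mres.status = ResolutionStatus.AMBIGUOUS
                mres.rule_applied += "+no_human_ortholog"
                mres.chosen = None
                cs.ambiguities.append(mres)
                continue
        cs.ambiguities.append(res)
    return cs
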