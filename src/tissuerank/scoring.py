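"""The prioritization core: affected-tissue base score, source combination, ranking.

A candidate gene g is scored against the user's affected tissue set T from
its tissue profile (per-tissue mean modified z-scores z̄_t, cross-tissue
median z̃):

    S_g = Σ_{t ∈ T}  z̄_t · (1 + ln(z̄_t / z̃))   if z̄_t > 0 and z̃ > 0
                     z̄_t                         otherwise

The log-ratio modifier rewards expression elevated in affected tissues
relative to the gene's own cross-tissue baseline, even when the absolute
level is modest; a non-positive z̄_t or baseline contributes the plain z̄_t
(negative values can only lower the score). Each evidence source (species ×
platform) is scored separately and the per-source scores are combined as a
weighted mean — human sources at weight 1, mouse sources at a user weight
in [0, 1]. Genes with data in only some sources are scored from what is
available; genes with no usable evidence are flagged and listed after all
scored genes. Ties share the smaller (competition) rank.

An optional variance adjustment damps ubiquitously high "housekeeping"
profiles: when every z̄_t is at least tau, the score is multiplied by
σ/(σ + c), where σ is the standard deviation of the gene's z̄_t across all
tissues — a perfectly flat profile is fully suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .candidates import CandidateSet
from .expression import Source, Species, TissueVocabulary, TissueZProfile
from .identifiers import GeneRegistry, OrthologPair

__all__ = [
    "AffectedTissueSet",
    "ScoringConfig",
    "GeneScore",
    "base_score",
    "missing_affected_tissues",
    "variance_adjust",
    "combine_sources",
    "prioritize",
    "write_results_tsv",
]


@dataclass(frozen=True)
class AffectedTissueSet:
    """The non-empty set T of tissues manifesting the phenotype."""

    tissues: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", frozenset(self.tissues))
        if not self.tissues:
            raise ValueError("affected tissue set must be non-empty")

    def validate_against(self, vocabulary: TissueVocabulary) -> None:
        unknown = sorted(self.tissues - vocabulary.labels)
        if unknown:
            raise ValueError(
                f"unknown affected tissue(s) {unknown}; "
                f"valid labels: {sorted(vocabulary.labels)}"
            )


@dataclass
class ScoringConfig:
    """Tunable scoring parameters.

    mouse_weight: relative contribution of mouse sources (human fixed at 1).
    variance_adjustment: enable housekeeping damping with threshold ``tau``
    (minimum per-tissue z̄ counting as ubiquitously high) and softening
    constant ``c`` (> 0). ``center`` is passed through to the modified
    z-score transform. Tie handling is fixed: competition ranks, with
    lexicographic gene id as display order within a tie.
    """

    mouse_weight: float = 1.0
    variance_adjustment: bool = False
    tau: float = 1.0
    c: float = 1.0
    center: str = "mean_as_printed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mouse_weight <= 1.0:
            raise ValueError(f"mouse_weight {self.mouse_weight} outside [0, 1]")
        if self.c <= 0:
            raise ValueError(f"softening constant c must be > 0, got {self.c}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ScoringConfig":
        kwargs: dict = {}
        if "mouse_weight" in mapping:
            kwargs["mouse_weight"] = float(mapping["mouse_weight"])
        if "variance_adjustment" in mapping:
            kwargs["variance_adjustment"] = mapping["variance_adjustment"].lower() in (
                "1", "true", "yes", "on",
            )
        for key in ("tau", "c"):
            if key in mapping:
                kwargs[key] = float(mapping[key])
        if "center" in mapping:
            kwargs["center"] = mapping["center"]
        return cls(**kwargs)


@dataclass
class GeneScore:
    """Scores and rank for one candidate gene."""

    gene_id: str
    per_source_score: dict[Source, float] = field(default_factory=dict)
    combined_score: Optional[float] = None
    rank: Optional[int] = None
    sources_used: frozenset[Source] = frozenset()
    no_data: bool = False
    provenance: list[tuple[str, str]] = field(default_factory=list)


def base_score(profile: TissueZProfile, affected: AffectedTissueSet) -> float:
    """Affected-tissue base score S_g for one gene in one evidence source.

    Affected tissues absent from the profile contribute 0 (use
    :func:`missing_affected_tissues` to report them).
    """
    z_med = profile.cross_tissue_median
    score = 0.0
    for tissue in sorted(affected.tissues):
        z_t = profile.per_tissue_mean_z.get(tissue)
        if z_t is None:
            continue
        if z_t > 0.0 and z_med > 0.0:
            score += z_t * (1.0 + math.log(z_t / z_med))
        else:
            score += z_t
    return score


def missing_affected_tissues(
    profile: TissueZProfile, affected: AffectedTissueSet
) -> list[str]:
    """Affected tissues with no observations for this gene/source."""
    return sorted(affected.tissues - profile.tissues)


def variance_adjust(score: float, profile: TissueZProfile, config: ScoringConfig) -> float:
    """Damp the score of ubiquitously highly expressed genes.

    Triggered only when min_t z̄_t >= tau; the factor σ/(σ + c) uses the
    population standard deviation of z̄_t over all of the gene's tissues.
    """
    z = np.fromiter(profile.per_tissue_mean_z.values(), dtype=float)
    if float(z.min()) < config.tau:
        return score
    sigma = float(np.std(z))
    return score * sigma / (sigma + config.c)


def combine_sources(
    per_source: Mapping[Source, float], config: ScoringConfig
) -> Optional[float]:
    """Weighted mean of per-source scores (human weight 1, mouse weight m).

    Returns None when the total weight is zero (mouse-only evidence with
    mouse_weight = 0): the gene cannot be ranked.
    """
    if not per_source:
        raise ValueError("combine_sources requires at least one per-source score")
    num = 0.0
    den = 0.0
    for source, s in per_source.items():
        w = 1.0 if Source(source).species is Species.HUMAN else config.mouse_weight
        num += w * s
        den += w
    if den == 0.0:
        return None
    return num / den


def _effective_weight(source: Source, config: ScoringConfig) -> float:
    return 1.0 if source.species is Species.HUMAN else config.mouse_weight


def prioritize(
    candidates: CandidateSet | Iterable[str],
    profiles_by_source: Mapping[Source, Mapping[str, TissueZProfile]],
    affected: AffectedTissueSet,
    config: ScoringConfig | None = None,
    orthologs: Sequence[OrthologPair] | None = None,
    vocabulary: TissueVocabulary | None = None,
) -> list[GeneScore]:
    """Score and rank candidate genes.

    Candidates are human canonical ids; when ``orthologs`` is given, mouse
    evidence sources are looked up under each candidate's mouse ortholog.
    Scored genes are sorted by descending combined score (competition
    ranking, ties share the smaller rank, lexicographic gene id as the
    display order); genes without usable evidence follow, flagged
    ``no_data`` and unranked.
    """
    config = config or ScoringConfig()
    if not isinstance(candidates, CandidateSet):
        candidates = CandidateSet.from_gene_ids(candidates)
    if not candidates.candidates:
        raise ValueError("empty candidate set")
    if vocabulary is not None:
        affected.validate_against(vocabulary)
    human_to_mouse = (
        {p.human_canonical_id: p.mouse_canonical_id for p in orthologs}
        if orthologs is not None
        else None
    )

    results: list[GeneScore] = []
    for cand in candidates.candidates:
        gene = cand.canonical_id
        per_source: dict[Source, float] = {}
        for source, profiles in profiles_by_source.items():
            source = Source(source)
            key = gene
            if source.species is Species.MOUSE and human_to_mouse is not None:
                key = human_to_mouse.get(gene)
                if key is None:
                    continue
            profile = profiles.get(key)
            if profile is None:
                continue
            s = base_score(profile, affected)
            if config.variance_adjustment:
                s = variance_adjust(s, profile, config)
            per_source[source] = s
        used = frozenset(
            src for src in per_source if _effective_weight(src, config) > 0.0
        )
        combined = combine_sources(per_source, config) if per_source else None
        if combined is None:
            used = frozenset()
        results.append(
            GeneScore(
                gene_id=gene,
                per_source_score=per_source,
                combined_score=combined,
                sources_used=used,
                no_data=combined is None,
                provenance=list(cand.provenance),
            )
        )

    scored = [r for r in results if not r.no_data]
    unscored = [r for r in results if r.no_data]
    if not scored:
        raise ValueError(
            "no candidate gene could be scored: the expression database may not "
            "cover these genes, or the selected tissues carry no data"
        )
    scored.sort(key=lambda r: (-r.combined_score, r.gene_id))
    rank = 0
    for i, r in enumerate(scored):
        if i == 0 or r.combined_score != scored[i - 1].combined_score:
            rank = i + 1
        r.rank = rank
    unscored.sort(key=lambda r: r.gene_id)
    return scored + unscored


def write_results_tsv(
    scores: Sequence[GeneScore],
    path: str | Path,
    registry: GeneRegistry | None = None,
) -> None:
    """Write ranked results as TSV (one score column per evidence source)."""
    path = Path(path)
    source_cols = [s for s in Source if any(s in r.per_source_score for r in scores)]
    header = (
        ["rank", "gene_id", "approved_symbol", "combined_score"]
        + [s.value for s in source_cols]
        + ["sources_used", "no_data", "provenance"]
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in scores:
            symbol = ""
            if registry is not None:
                rec = registry.get(r.gene_id)
                symbol = rec.approved_symbol if rec else ""
            row = [
                str(r.rank) if r.rank is not None else "NA",
                r.gene_id,
                symbol,
                f"{r.combined_score:.6g}" if r.combined_score is not None else "NA",
            ]
            for s in source_cols:
                v = r.per_source_score.get(s)
                row.append(f"{v:.6g}" if v is not None else "NA")
            row.append(";".join(sorted(s.value for s in r.sources_used)))
            row.append("yes" if r.no_data else "no")
            row.append(";".join(f"{k}:{d}" for k, d in r.provenance))
            fh.write("\t".join(row) + "\n")
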