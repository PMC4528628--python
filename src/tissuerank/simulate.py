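"""Synthetic expression databases and gene tables with planted signal.

Generates everything the pipeline consumes — expression experiments across
the four evidence sources, a two-species gene model with aliases and
accessions, and a one-to-one ortholog table — plus a truth table of planted
tissue-specific signals, so scoring and benchmarking can be exercised
end-to-end with known ground truth.

Background expression is i.i.d. log-normal per (gene, experiment):
each observation is exp(mu + b_g + N(0, sigma)), where mu and sigma are the
background log-mean and log-sd and b_g is an optional per-gene baseline
offset (default 0, i.e. fully i.i.d.; a positive ``gene_baseline_log_sd``
creates genes with conserved high/low overall expression — shared with the
mouse ortholog — useful for exercising the housekeeping-gene adjustment).
A planted (gene, tissue) signal adds its effect size on the log scale —
i.e. multiplicatively on the expression scale — in every experiment of that
tissue, so the full modified z-score pipeline, not just the score, is
exercised. Background observations are i.i.d.: the generator does not
emulate correlated tissue programs, platform artifacts or count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import (
    ExperimentDataset,
    Source,
    Species,
    TissueVocabulary,
    write_expression_table,
)
from .identifiers import GeneRecord, OrthologPair, write_gene_model, write_ortholog_table

#: Default tissue panel (available in both species).
DEFAULT_TISSUES = (
    "brain", "heart", "kidney", "liver", "lung",
    "muscle", "ovary", "skin", "spleen", "testis",
)

_N_CHROMOSOMES = 5
_GENE_BLOCK = 10_000  # spacing between consecutive gene starts on a chromosome
_GENE_LENGTH = 5_000


def _default_experiments() -> dict[Source, int]:
    return {src: 2 for src in Source}


@dataclass(frozen=True)
class PlantedSignal:
    """A gene given elevated expression in a set of tissues."""

    gene: str
    tissues: frozenset[str]
    effect: float  # additive shift in log-expression units

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", frozenset(self.tissues))
        if self.effect < 0:
            raise ValueError(f"effect size must be >= 0, got {self.effect}")
        if not self.tissues:
            raise ValueError(f"planted signal for {self.gene!r} names no tissues")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe the standard test conditions: 500 genes, the 10-tissue
    panel, two experiments per tissue in each of the four evidence sources,
    i.i.d. log-normal background exp(N(1, 1)), 90% of genes with a
    one-to-one mouse ortholog.
    """

    n_genes: int = 500
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    experiments_per_tissue: Mapping[Source, int] = field(default_factory=_default_experiments)
    planted: tuple[PlantedSignal, ...] = ()
    background_log_mean: float = 1.0
    background_log_sd: float = 1.0
    gene_baseline_log_sd: float = 0.0
    ortholog_fraction: float = 0.9
    ambiguous_alias_count: int = 2
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", tuple(self.tissues))
        object.__setattr__(self, "planted", tuple(self.planted))
        object.__setattr__(
            self,
            "experiments_per_tissue",
            {Source(k): int(v) for k, v in dict(self.experiments_per_tissue).items()},
        )
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if not 0.0 <= self.ortholog_fraction <= 1.0:
            raise ValueError("ortholog_fraction outside [0, 1]")
        gene_ids = set(self.human_gene_ids())
        for p in self.planted:
            if p.gene not in gene_ids:
                raise ValueError(f"planted gene {p.gene!r} not among generated genes")
            unknown = p.tissues - set(self.tissues)
            if unknown:
                raise ValueError(f"planted tissues {sorted(unknown)} not in the panel")

    def human_gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SyntheticSpec":
        """Build a spec from a flat key=value mapping (strings)."""
        kwargs: dict = {}
        for key in ("n_genes", "ambiguous_alias_count", "seed"):
            if key in mapping:
                kwargs[key] = int(mapping[key])
        for key in (
            "background_log_mean", "background_log_sd", "gene_baseline_log_sd",
            "ortholog_fraction", "overlap_fraction",
        ):
            if key in mapping:
                kwargs[key] = float(mapping[key])
        if "tissues" in mapping:
            kwargs["tissues"] = tuple(t for t in mapping["tissues"].split(";") if t)
        if "experiments_per_tissue" in mapping:
            pairs = dict(
                item.split("=") for item in mapping["experiments_per_tissue"].split(";")
            )
            kwargs["experiments_per_tissue"] = {Source(k): int(v) for k, v in pairs.items()}
        if "planted" in mapping:
            planted = []
            for item in mapping["planted"].split("|"):
                if not item:
                    continue
                gene, tissues, effect = item.split(":")
                planted.append(
                    PlantedSignal(gene, frozenset(tissues.split(";")), float(effect))
                )
            kwargs["planted"] = tuple(planted)
        return cls(**kwargs)


# Independent deterministic RNG streams per concern, so each generator
# operation is reproducible on its own from spec.seed.
_STREAM_BASELINE = 7
_STREAM_ORTHOLOG = 17
_STREAM_VALUES = 29
_STREAM_OVERLAP = 11


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def ortholog_map(spec: SyntheticSpec) -> dict[str, str]:
    """Deterministic human→mouse id map for the spec's ortholog fraction."""
    ids = spec.human_gene_ids()
    n_pairs = int(round(spec.ortholog_fraction * len(ids)))
    rng = _rng(spec, _STREAM_ORTHOLOG)
    chosen = sorted(rng.choice(len(ids), size=n_pairs, replace=False).tolist())
    return {ids[i]: "M" + ids[i][1:] for i in chosen}


def _gene_baselines(spec: SyntheticSpec) -> np.ndarray:
    return _rng(spec, _STREAM_BASELINE).normal(
        0.0, spec.gene_baseline_log_sd, spec.n_genes
    )


def generate_database(
    spec: SyntheticSpec,
) -> tuple[list[ExperimentDataset], pd.DataFrame]:
    """Generate the expression database and the planted-truth table.

    Returns the experiments (one per source × tissue × replicate) and a
    DataFrame with columns (gene, tissue, effect), one row per planted
    (gene, tissue) pair. Mouse experiments are keyed by mouse canonical
    ids; planted effects propagate to the mouse ortholog when one exists.
    """
    human_ids = spec.human_gene_ids()
    baselines = _gene_baselines(spec)
    h2m = ortholog_map(spec)
    mouse_idx = [i for i, g in enumerate(human_ids) if g in h2m]
    mouse_ids = [h2m[human_ids[i]] for i in mouse_idx]

    effects_h: dict[tuple[str, str], float] = {}
    for p in spec.planted:
        for t in p.tissues:
            effects_h[(p.gene, t)] = effects_h.get((p.gene, t), 0.0) + p.effect

    rng = _rng(spec, _STREAM_VALUES)
    datasets: list[ExperimentDataset] = []
    for source in Source:  # fixed enum order keeps RNG consumption stable
        n_exp = spec.experiments_per_tissue.get(source, 0)
        if source.species is Species.HUMAN:
            ids, base = human_ids, baselines
        else:
            ids, base = mouse_ids, baselines[mouse_idx]
        if n_exp == 0 or len(ids) < 3:
            continue
        if source.species is Species.HUMAN:
            eff_ids = human_ids
        else:
            eff_ids = [human_ids[i] for i in mouse_idx]  # effects keyed by human gene
        for tissue in spec.tissues:
            shift = np.array(
                [effects_h.get((g, tissue), 0.0) for g in eff_ids], dtype=float
            )
            for rep in range(1, n_exp + 1):
                noise = rng.normal(0.0, spec.background_log_sd, len(ids))
                logv = spec.background_log_mean + base + noise + shift
                datasets.append(
                    ExperimentDataset(
                        experiment_id=f"{source.value}.{tissue}.r{rep}",
                        species=source.species,
                        platform=source.platform,
                        tissue=tissue,
                        values=dict(zip(ids, np.exp(logv).tolist())),
                    )
                )
    truth = pd.DataFrame(
        [(g, t, e) for (g, t), e in sorted(effects_h.items())],
        columns=["gene", "tissue", "effect"],
    )
    return datasets, truth


def generate_gene_model(spec: SyntheticSpec) -> list[GeneRecord]:
    """Synthetic two-species gene model with aliases and accessions.

    Human genes are laid out round-robin over 5 chromosomes in
    non-overlapping blocks (two exons each); ``overlap_fraction`` > 0 pulls
    that fraction of spans back over their left neighbour. Each gene gets a
    unique alias; ``ambiguous_alias_count`` shared aliases are attached to
    consecutive gene pairs to exercise the resolver.
    """
    ids = spec.human_gene_ids()
    h2m = ortholog_map(spec)
    overlap_rng = _rng(spec, _STREAM_OVERLAP)
    n_overlap = int(round(spec.overlap_fraction * len(ids)))
    overlapping = set(
        overlap_rng.choice(len(ids), size=n_overlap, replace=False).tolist()
    ) if n_overlap else set()

    ambiguous: dict[int, str] = {}
    for k in range(spec.ambiguous_alias_count):
        alias = f"SHARED{k + 1}"
        for gi in (2 * k, 2 * k + 1):
            if gi < len(ids):
                ambiguous.setdefault(gi, alias)

    records: list[GeneRecord] = []
    for species in (Species.HUMAN, Species.MOUSE):
        if species is Species.HUMAN:
            members = list(enumerate(ids))
        else:
            members = [(i, h2m[g]) for i, g in enumerate(ids) if g in h2m]
        per_chrom_pos: dict[str, int] = {}
        for i, canonical in members:
            chrom = f"chr{(i % _N_CHROMOSOMES) + 1}"
            slot = per_chrom_pos.get(chrom, 0)
            per_chrom_pos[chrom] = slot + 1
            start = 1 + slot * _GENE_BLOCK
            if species is Species.HUMAN and i in overlapping and slot > 0:
                # pull the span back past the inter-gene gap into the left
                # neighbour (blocks are _GENE_BLOCK apart, genes _GENE_LENGTH long)
                start -= _GENE_BLOCK - _GENE_LENGTH // 2
            end = start + _GENE_LENGTH - 1
            exons = ((start, start + 999), (start + 3000, start + 3999))
            num = i + 1
            if species is Species.HUMAN:
                symbol = f"GENE{num}"
                aliases = {f"ALIAS{num}"}
                if i in ambiguous:
                    aliases.add(ambiguous[i])
                ensembl = f"ENSG{num:011d}"
                entrez = str(1000 + num)
                refseq = f"NM_{num:06d}"
            else:
                symbol = f"Gene{num}"
                aliases = {f"Alias{num}"}
                ensembl = f"ENSMUSG{num:011d}"
                entrez = str(900000 + num)
                refseq = f"NM_9{num:05d}"
            records.append(
                GeneRecord(
                    canonical_id=canonical,
                    approved_symbol=symbol,
                    species=species,
                    chromosome=chrom,
                    span_start=start,
                    span_end=end,
                    aliases=frozenset(aliases),
                    ensembl_id=ensembl,
                    entrez_id=entrez,
                    refseq_id=refseq,
                    exons=exons,
                )
            )
    return records


def generate_ortholog_pairs(spec: SyntheticSpec) -> list[OrthologPair]:
    return [OrthologPair(h, m) for h, m in sorted(ortholog_map(spec).items())]


def generate_identifier_tables(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the gene model and ortholog TSVs; returns {name: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_model_path = out_dir / "gene_model.tsv"
    ortholog_path = out_dir / "orthologs.tsv"
    write_gene_model(generate_gene_model(spec), gene_model_path)
    write_ortholog_table(generate_ortholog_pairs(spec), ortholog_path)
    return {"gene_model": gene_model_path, "orthologs": ortholog_path}


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces, ready for the pipeline."""

    spec: SyntheticSpec
    datasets: list[ExperimentDataset]
    truth: pd.DataFrame
    gene_model: list[GeneRecord]
    orthologs: list[OrthologPair]

    @property
    def vocabulary(self) -> TissueVocabulary:
        return TissueVocabulary.from_datasets(self.datasets)


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    datasets, truth = generate_database(spec)
    return SyntheticBundle(
        spec=spec,
        datasets=datasets,
        truth=truth,
        gene_model=generate_gene_model(spec),
        orthologs=generate_ortholog_pairs(spec),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle's expression, gene model, ortholog and truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "gene_model": out_dir / "gene_model.tsv",
        "orthologs": out_dir / "orthologs.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression_table(bundle.datasets, paths["expression"])
    write_gene_model(bundle.gene_model, paths["gene_model"])
    write_ortholog_table(bundle.orthologs, paths["orthologs"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
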