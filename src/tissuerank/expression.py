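"""Tissue-specific expression database model and robust standardization.

The database is a collection of experiments, each holding one normalized
expression value per gene for a single (species, platform, tissue) stratum.
Within every experiment the expression vector is transformed to modified
z-scores,

    z_e = 0.6745 * (e - center) / MAD,      MAD = median(|e - median(E)|),

a robust standardization resistant to the heavy right tail of expression
data. Two centering conventions are supported: ``mean_as_printed`` (center
is the experiment mean, the package default) and ``median_standard`` (the
classical Iglewicz–Hoaglin form centered on the median). Per-gene tissue
profiles then summarize a gene's modified z-scores as the mean per tissue
(z̄_t) together with the median of those per-tissue means across tissues
(z̃), within one evidence source (species × platform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateExperimentError, InputFormatError

#: Scaling constant making the modified z-score comparable to a standard
#: normal deviate (0.6745 is the normal quartile Φ⁻¹(0.75)).
MODIFIED_Z_CONSTANT = 0.6745

#: Supported centering conventions for :func:`modified_zscores`.
CENTER_CONVENTIONS = ("mean_as_printed", "median_standard")


class Species(str, Enum):
    HUMAN = "human"
    MOUSE = "mouse"


class Platform(str, Enum):
    MICROARRAY = "microarray"
    RNASEQ = "rnaseq"


class Source(str, Enum):
    """Evidence source: one (species × platform) stratum, scored separately."""

    HUMAN_MICROARRAY = "human_microarray"
    HUMAN_RNASEQ = "human_rnaseq"
    MOUSE_MICROARRAY = "mouse_microarray"
    MOUSE_RNASEQ = "mouse_rnaseq"

    @property
    def species(self) -> Species:
        return Species(self.value.split("_")[0])

    @property
    def platform(self) -> Platform:
        return Platform(self.value.split("_")[1])

    @classmethod
    def from_parts(cls, species: Species | str, platform: Platform | str) -> "Source":
        return cls(f"{Species(species).value}_{Platform(platform).value}")


@dataclass
class ExperimentDataset:
    """One experiment: a normalized expression vector over genes.

    ``values`` maps gene id -> normalized expression value; values must be
    finite and non-negative, and at least 3 genes are required (median and
    MAD are degenerate below that).
    """

    experiment_id: str
    species: Species
    platform: Platform
    tissue: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        self.platform = Platform(self.platform)
        if not self.tissue:
            raise ValueError(f"experiment {self.experiment_id!r}: empty tissue label")
        if len(self.values) < 3:
            raise DegenerateExperimentError(
                f"experiment {self.experiment_id!r} has {len(self.values)} genes; "
                "at least 3 are required"
            )
        for gene, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"experiment {self.experiment_id!r}, gene {gene!r}: "
                    f"expression value {v!r} is not finite and non-negative"
                )

    @property
    def source(self) -> Source:
        return Source.from_parts(self.species, self.platform)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProbeMapping:
    """A microarray probe and the set of genes it hybridizes to."""

    probe_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise ValueError(f"probe {self.probe_id!r}: empty gene set")


def filter_ambiguous_probes(mappings: Sequence[ProbeMapping]) -> list[ProbeMapping]:
    """Discard probes hybridizing to more than one distinct gene.

    Keeps input order; ambiguous probes carry no usable per-gene signal.
    """
    return [m for m in mappings if len(m.gene_ids) == 1]


@dataclass
class TissueVocabulary:
    """The controlled set of tissue labels, with per-species availability."""

    labels: frozenset[str]
    species_by_label: dict[str, frozenset[Species]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = frozenset(self.labels)
        if any(not lab for lab in self.labels):
            raise ValueError("tissue labels must be non-empty strings")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    @classmethod
    def from_datasets(cls, datasets: Iterable[ExperimentDataset]) -> "TissueVocabulary":
        species_by_label: dict[str, set[Species]] = {}
        for ds in datasets:
            species_by_label.setdefault(ds.tissue, set()).add(ds.species)
        return cls(
            labels=frozenset(species_by_label),
            species_by_label={t: frozenset(s) for t, s in species_by_label.items()},
        )


@dataclass
class TissueZProfile:
    """A gene's per-tissue mean modified z-scores within one evidence source.

    ``per_tissue_mean_z`` maps tissue -> z̄_t; ``cross_tissue_median`` is z̃,
    the median of the stored per-tissue means.
    """

    gene_id: str
    source: Source
    per_tissue_mean_z: dict[str, float]
    cross_tissue_median: float

    def __post_init__(self) -> None:
        self.source = Source(self.source)
        if not self.per_tissue_mean_z:
            raise ValueError(f"gene {self.gene_id!r}: empty tissue profile")
        for t, z in self.per_tissue_mean_z.items():
            if not math.isfinite(z):
                raise ValueError(f"gene {self.gene_id!r}, tissue {t!r}: non-finite z̄")

    def validate(self) -> None:
        """Recompute z̃ from the stored per-tissue means and check it."""
        expected = float(np.median(list(self.per_tissue_mean_z.values())))
        if not math.isclose(self.cross_tissue_median, expected, abs_tol=1e-12):
            raise ValueError(
                f"gene {self.gene_id!r}: stored cross-tissue median "
                f"{self.cross_tissue_median} != recomputed {expected}"
            )

    @property
    def tissues(self) -> frozenset[str]:
        return frozenset(self.per_tissue_mean_z)


def modified_zscores(
    dataset: ExperimentDataset, center: str = "mean_as_printed"
) -> dict[str, float]:
    """Modified z-scores of one experiment's expression vector.

    ``center="mean_as_printed"`` centers on the experiment mean;
    ``center="median_standard"`` centers on the median. The denominator is
    always the MAD about the median, scaled by 0.6745. A zero MAD (more
    than half the values identical) falls back to the mean absolute
    deviation about the median; if that is also zero every score is 0.
    """
    if center not in CENTER_CONVENTIONS:
        raise ValueError(f"unknown center convention {center!r}; use one of {CENTER_CONVENTIONS}")
    genes = list(dataset.values)
    vals = np.asarray([dataset.values[g] for g in genes], dtype=float)
    if vals.size < 3:
        raise DegenerateExperimentError(
            f"experiment {dataset.experiment_id!r} is degenerate ({vals.size} genes)"
        )
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    if mad == 0.0:
        mad = float(np.mean(np.abs(vals - med)))
    if mad == 0.0:  # all values identical: no dispersion, no signal
        return dict.fromkeys(genes, 0.0)
    c = float(np.mean(vals)) if center == "mean_as_printed" else med
    z = MODIFIED_Z_CONSTANT * (vals - c) / mad
    return dict(zip(genes, z.tolist()))


def build_tissue_profiles(
    datasets: Sequence[ExperimentDataset],
    source: Source | str,
    center: str = "mean_as_printed",
    vocabulary: TissueVocabulary | None = None,
) -> dict[str, TissueZProfile]:
    """Per-gene tissue profiles for one evidence source.

    For each gene, z̄_t is the mean of its modified z-scores over every
    experiment of tissue t in which the gene is observed (genes missing
    from an experiment are simply absent — no zero imputation), and z̃ is
    the median of the gene's z̄_t values over its observed tissues.
    """
    source = Source(source)
    if not datasets:
        return {}
    frames = []
    for ds in datasets:
        if ds.source != source:
            raise ValueError(
                f"experiment {ds.experiment_id!r} is {ds.source.value}, expected {source.value}"
            )
        if vocabulary is not None and ds.tissue not in vocabulary:
            raise ValueError(f"tissue label {ds.tissue!r} not in vocabulary")
        z = modified_zscores(ds, center=center)
        frames.append(
            pd.DataFrame({"gene": list(z), "tissue": ds.tissue, "z": list(z.values())})
        )
    long = pd.concat(frames, ignore_index=True)
    mat = long.groupby(["gene", "tissue"], sort=False)["z"].mean().unstack("tissue")
    arr = mat.to_numpy(dtype=float)
    tissue_labels = np.asarray([str(t) for t in mat.columns], dtype=object)
    medians = np.nanmedian(arr, axis=1)
    profiles: dict[str, TissueZProfile] = {}
    for i, gene in enumerate(mat.index):
        row = arr[i]
        mask = ~np.isnan(row)
        profiles[str(gene)] = TissueZProfile(
            gene_id=str(gene),
            source=source,
            per_tissue_mean_z=dict(zip(tissue_labels[mask], row[mask].tolist())),
            cross_tissue_median=float(medians[i]),
        )
    return profiles


def build_profiles_by_source(
    datasets: Sequence[ExperimentDataset],
    center: str = "mean_as_printed",
    vocabulary: TissueVocabulary | None = None,
) -> dict[Source, dict[str, TissueZProfile]]:
    """Group experiments by evidence source and build profiles per source."""
    by_source: dict[Source, list[ExperimentDataset]] = {}
    for ds in datasets:
        by_source.setdefault(ds.source, []).append(ds)
    return {
        src: build_tissue_profiles(group, src, center=center, vocabulary=vocabulary)
        for src, group in by_source.items()
    }


# --------------------------------------------------------------------------
# Tabular IO
#
# Expression table: UTF-8 TSV with header
#   experiment_id  species  platform  tissue  gene_id  value
# one row per (experiment, gene); '#' starts a comment line.
# --------------------------------------------------------------------------

_EXPR_COLUMNS = ("experiment_id", "species", "platform", "tissue", "gene_id", "value")


def read_expression_table(path: str | Path) -> list[ExperimentDataset]:
    """Read an expression table TSV into experiments (first-seen order)."""
    path = Path(path)
    meta: dict[str, tuple[str, str, str]] = {}
    values: dict[str, dict[str, float]] = {}
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _EXPR_COLUMNS:
                    raise InputFormatError(
                        f"bad header {fields!r}; expected {list(_EXPR_COLUMNS)}", lineno
                    )
                header_seen = True
                continue
            if len(fields) != len(_EXPR_COLUMNS):
                raise InputFormatError(
                    f"expected {len(_EXPR_COLUMNS)} columns, got {len(fields)}", lineno
                )
            exp_id, species, platform, tissue, gene, value_text = fields
            try:
                species_e = Species(species)
                platform_e = Platform(platform)
            except ValueError as exc:
                raise InputFormatError(str(exc), lineno) from None
            try:
                value = float(value_text)
            except ValueError:
                raise InputFormatError(f"unparseable value {value_text!r}", lineno) from None
            if not math.isfinite(value) or value < 0:
                raise InputFormatError(
                    f"expression value {value_text!r} must be finite and >= 0", lineno
                )
            if exp_id in meta:
                if meta[exp_id] != (species_e.value, platform_e.value, tissue):
                    raise InputFormatError(
                        f"experiment {exp_id!r} has inconsistent species/platform/tissue",
                        lineno,
                    )
                if gene in values[exp_id]:
                    raise InputFormatError(
                        f"duplicate (gene, experiment) row: {gene!r} in {exp_id!r}", lineno
                    )
            else:
                meta[exp_id] = (species_e.value, platform_e.value, tissue)
                values[exp_id] = {}
            values[exp_id][gene] = value
    if not header_seen:
        raise InputFormatError(f"{path}: empty expression table (no header)")
    return [
        ExperimentDataset(
            experiment_id=exp_id,
            species=Species(meta[exp_id][0]),
            platform=Platform(meta[exp_id][1]),
            tissue=meta[exp_id][2],
            values=values[exp_id],
        )
        for exp_id in meta
    ]


def write_expression_table(
    datasets: Iterable[ExperimentDataset], path: str | Path
) -> None:
    """Write experiments as an expression table TSV (full decimal precision).

    Rows are sorted by (experiment_id, gene_id) so output is deterministic
    and write-then-read round-trips exactly.
    """
    path = Path(path)
    rows = []
    for ds in datasets:
        for gene in sorted(ds.values):
            rows.append(
                (ds.experiment_id, ds.species.value, ds.platform.value, ds.tissue, gene,
                 repr(ds.values[gene]))
            )
    rows.sort(key=lambda r: (r[0], r[4]))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_EXPR_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
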