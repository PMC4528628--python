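"""Benchmarking: decoy sampling, rank-cutoff ROC/AUC, rank statistics, KS test.

A benchmark replicate ranks one known disease gene against a set of
randomly drawn decoy genes. Treating the disease gene as the positive and
the decoys as negatives, a confusion matrix exists at every integer rank
cutoff; sensitivity vs. 1−specificity over those cutoffs, pooled over
replicates, gives a ROC curve whose trapezoidal area equals the
Mann–Whitney probability that a positive outranks a negative (ties ½).
An AUC of 0.5 is random performance, 1.0 is a perfect classifier.

Rank summaries (mean rank ± sample SD, mean reciprocal rank) and a
one-sided two-sample Kolmogorov–Smirnov test of the core hypothesis —
disease genes are more highly expressed in affected than unaffected
tissues — complete the evaluation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .expression import Source, TissueZProfile
from .identifiers import OrthologPair
from .scoring import AffectedTissueSet, ScoringConfig, prioritize

__all__ = [
    "BenchmarkRun",
    "RocResult",
    "KSResult",
    "RankStats",
    "sample_decoys",
    "roc_from_ranks",
    "auc_mann_whitney",
    "mean_per_replicate_auc",
    "rank_stats",
    "ks_affected_vs_unaffected",
    "benchmark_disease_gene",
]

#: Decoy set sizes used by default.
DEFAULT_DECOY_SIZES = (50, 100, 200, 500)
#: Default number of replicates per (gene, size).
DEFAULT_REPLICATES = 30


@dataclass
class BenchmarkRun:
    """Replicate ranks of one disease gene at one decoy size."""

    disease_gene: str
    affected_tissues: frozenset[str]
    decoy_size: int
    ranks: list[int]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("a benchmark run needs at least one replicate")
        for r in self.ranks:
            if not 1 <= r <= self.decoy_size + 1:
                raise ValueError(
                    f"rank {r} outside [1, {self.decoy_size + 1}] "
                    f"for decoy size {self.decoy_size}"
                )


@dataclass
class RocResult:
    """ROC points ((1−specificity, sensitivity) per integer cutoff) and AUC."""

    points: list[tuple[float, float]]
    auc: float


class RankStats(NamedTuple):
    mean_rank: float
    sd_rank: float
    mean_reciprocal_rank: float
    sd_defined: bool


class KSDirection(str, Enum):
    AFFECTED_GREATER = "affected_greater"
    AFFECTED_LESS = "affected_less"


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    direction: KSDirection

    def __post_init__(self) -> None:
        self.direction = KSDirection(self.direction)
        if not 0.0 <= self.d_statistic <= 1.0:
            raise ValueError(f"KS D {self.d_statistic} outside [0, 1]")


def sample_decoys(
    universe: Iterable[str],
    disease_gene: str,
    size: int,
    n_replicates: int,
    seed: int,
) -> list[list[str]]:
    """Random decoy candidate sets, each containing the disease gene.

    Each replicate draws ``size`` genes uniformly without replacement from
    the universe excluding the disease gene. Reproducible under ``seed``.
    """
    pool = sorted(set(universe) - {disease_gene})
    if len(pool) < size:
        raise ValueError(
            f"universe has only {len(pool)} genes besides {disease_gene!r}; "
            f"cannot draw {size} decoys"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_replicates):
        idx = rng.choice(len(pool), size=size, replace=False)
        sets.append([disease_gene] + [pool[i] for i in sorted(idx)])
    return sets


def _pooled_counts(runs: Sequence[BenchmarkRun]) -> tuple[np.ndarray, int, int]:
    if not runs:
        raise ValueError("no benchmark runs supplied")
    sizes = {run.decoy_size for run in runs}
    if len(sizes) > 1:
        raise ValueError(f"runs mix decoy sizes {sorted(sizes)}; pool one size at a time")
    n = sizes.pop()
    ranks = np.concatenate([np.asarray(run.ranks, dtype=int) for run in runs])
    return ranks, n, len(ranks)


def roc_from_ranks(runs: Sequence[BenchmarkRun]) -> RocResult:
    """Pooled rank-cutoff ROC curve and trapezoidal AUC.

    At cutoff k every replicate's top-k candidates are called positive:
    the disease gene is a true positive iff its rank <= k, and the
    remaining k − [rank <= k] called candidates are false positives.
    Replicates are pooled into a single curve.
    """
    ranks, n, n_rep = _pooled_counts(runs)
    total_neg = n_rep * n
    points: list[tuple[float, float]] = []
    for k in range(0, n + 2):
        tp = int(np.count_nonzero(ranks <= k))
        fp = n_rep * min(k, n + 1) - tp
        points.append((fp / total_neg, tp / n_rep))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=points, auc=auc)


def auc_mann_whitney(runs: Sequence[BenchmarkRun]) -> float:
    """AUC as the fraction of positive–decoy pairs correctly ordered (ties ½).

    Computed on the same pooled data as :func:`roc_from_ranks`: each
    replicate contributes its disease-gene rank as a positive and the
    remaining ranks 1..n+1 as negatives. Equals the trapezoidal AUC.
    """
    ranks, n, n_rep = _pooled_counts(runs)
    counts = np.bincount(ranks, minlength=n + 2)  # counts[r] = replicates at rank r
    wins = 0.0
    ties = 0.0
    for r in ranks:
        # negatives strictly worse (larger rank) than this positive
        wins += n_rep * (n + 1 - r) - int(np.count_nonzero(ranks > r))
        # negatives at exactly rank r (absent only where the positive sits there)
        ties += n_rep - counts[r]
    return float((wins + 0.5 * ties) / (n_rep * n_rep * n))


def mean_per_replicate_auc(runs: Sequence[BenchmarkRun]) -> float:
    """Average of single-replicate AUCs ((n + 1 − rank)/n per replicate)."""
    ranks, n, _ = _pooled_counts(runs)
    return float(np.mean((n + 1 - ranks) / n))


def rank_stats(run: BenchmarkRun) -> RankStats:
    """Mean rank, sample SD (n−1) and mean reciprocal rank over replicates.

    With a single replicate the SD is undefined and reported as 0 with
    ``sd_defined=False``.
    """
    ranks = np.asarray(run.ranks, dtype=float)
    mean = float(ranks.mean())
    if ranks.size >= 2:
        sd, defined = float(ranks.std(ddof=1)), True
    else:
        sd, defined = 0.0, False
    mrr = float(np.mean(1.0 / ranks))
    return RankStats(mean, sd, mrr, defined)


def ks_affected_vs_unaffected(
    profiles: Mapping[str, TissueZProfile],
    associations: Sequence[tuple[str, Iterable[str]]],
    direction: KSDirection | str = KSDirection.AFFECTED_GREATER,
) -> KSResult:
    """One-sided two-sample KS test: affected vs. unaffected tissue z̄ values.

    Pools, over every (gene, affected tissues) association, the gene's
    per-tissue mean z-scores in its affected tissues (sample A) and in all
    its other tissues (sample B), then tests whether A is stochastically
    greater than B (default direction) with the asymptotic one-sided
    two-sample KS statistic.
    """
    direction = KSDirection(direction)
    affected_vals: list[float] = []
    other_vals: list[float] = []
    for gene, tissues in associations:
        profile = profiles.get(gene)
        if profile is None:
            continue
        tissues = set(tissues)
        for t, z in profile.per_tissue_mean_z.items():
            (affected_vals if t in tissues else other_vals).append(z)
    if len(affected_vals) < 2 or len(other_vals) < 2:
        raise ValueError(
            f"need >= 2 values per sample; got {len(affected_vals)} affected, "
            f"{len(other_vals)} unaffected"
        )
    # scipy alternative='less': CDF of the first sample lies below the
    # second's, i.e. the first sample is stochastically greater.
    alternative = "less" if direction is KSDirection.AFFECTED_GREATER else "greater"
    res = stats.ks_2samp(affected_vals, other_vals, alternative=alternative, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), direction)


def benchmark_disease_gene(
    disease_gene: str,
    affected: AffectedTissueSet,
    profiles_by_source: Mapping[Source, Mapping[str, TissueZProfile]],
    universe: Iterable[str],
    size: int,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    config: ScoringConfig | None = None,
    orthologs: Sequence[OrthologPair] | None = None,
) -> BenchmarkRun:
    """Rank a disease gene against random decoy sets, one rank per replicate.

    A disease gene that cannot be scored in a replicate (no expression
    evidence) is assigned the worst possible rank, size + 1.
    """
    decoy_sets = sample_decoys(universe, disease_gene, size, n_replicates, seed)
    ranks: list[int] = []
    for candidate_ids in decoy_sets:
        scores = prioritize(
            candidate_ids, profiles_by_source, affected, config, orthologs=orthologs
        )
        rank = next(
            (s.rank for s in scores if s.gene_id == disease_gene and s.rank is not None),
            size + 1,
        )
        ranks.append(rank)
    return BenchmarkRun(
        disease_gene=disease_gene,
        affected_tissues=frozenset(affected.tissues),
        decoy_size=size,
        ranks=ranks,
        seed=seed,
    )
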