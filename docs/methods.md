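# Methods

## Model and assumptions

`tissuerank` scores a candidate gene by how much its expression in the
user-designated affected tissues exceeds its own cross-tissue baseline,
under the working hypothesis that genes causing a tissue-restricted
phenotype are more highly expressed in the affected tissue(s) than
elsewhere. The method deliberately uses *only* baseline expression in
normal tissues: no disease annotations, networks or seed genes, so it is
free of the bias toward well-characterized genes that guilt-by-association
methods carry. The converse limitations follow directly: genes that act
through loss of a ubiquitously expressed product, through aberrant
activation of a normally silent gene, or in a tissue absent from the
database will not score well, and the user must name the biologically
affected tissue (e.g. liver, not blood, for a clotting-factor disorder).

### Robust standardization

Expression values are standardized per experiment, across genes:

    z_e = 0.6745 · (e − center) / MAD,    MAD = median |e − Ẽ|

with Ẽ the experiment median. The MAD denominator makes the score robust to
the heavy right tail of expression data, and standardizing within an
experiment makes values comparable across platforms and laboratories. Two
centering conventions are offered: `mean_as_printed` (center = experiment
mean; the package default) and `median_standard` (center = median, the
classical Iglewicz–Hoaglin form). The mean-centered default is the
documented behaviour of this scoring scheme even though the median-centered
form is the textbook one; on symmetric data the two agree exactly. Whether
standardization should instead run per gene across experiments is a
genuinely open alternative; per-experiment-across-genes is implemented.

Degenerate cases: an experiment needs ≥ 3 genes (median and MAD are
meaningless below that — an error). When MAD = 0 (more than half the
values identical) the mean absolute deviation about the median is
substituted, keeping the 0.6745 scale constant for continuity; if that is
also 0 all scores are 0 ("no dispersion, no signal"). Genes absent from an
experiment are simply absent — absence is not imputed as zero expression.

### Tissue profiles and the base score

Per evidence source (human/mouse × microarray/RNA-seq), a gene's profile
is z̄_t — the mean of its modified z-scores over all experiments of tissue
t — together with z̃, the median of its z̄_t over observed tissues. For an
affected tissue set T:

    S_g = Σ_{t ∈ T}  z̄_t (1 + ln(z̄_t / z̃))   if z̄_t > 0 and z̃ > 0
                     z̄_t                        otherwise

The log-ratio term boosts tissue-relative elevation even at modest absolute
levels and penalizes (via a negative logarithm) expression below baseline.
The piecewise condition requires both arguments of the ratio positive —
the logarithm is undefined otherwise — and the fallback contributes the
plain z̄_t, so a negative z̄_t can only lower the score. Affected tissues
missing from a gene's profile contribute 0 (and are reportable) rather
than invalidating the source, consistent with tolerating incomplete data.

Note a consequence of the formula worth knowing: as z̃ → 0⁺ the ratio
z̄_t/z̃ and hence the score diverge, so genes whose cross-tissue median
hovers just above zero can receive very large boosts. On real, non-negative
log-scale expression data z̃ is typically bounded away from zero; the
synthetic tests exercise this regime deliberately.

### Housekeeping variance adjustment (off by default)

Ubiquitously high genes can accumulate score in every tissue. When enabled,
a gene whose minimum z̄_t over all tissues is at least `tau` (default 1.0,
z-score units) has its score multiplied by σ/(σ + c), where σ is the
population standard deviation of its z̄_t across tissues and `c` > 0
(default 1.0) a softening constant. A perfectly flat high profile (σ = 0)
is fully suppressed; strongly patterned profiles are barely touched. The
gate-plus-factor form is this package's concrete realization of
variance-based damping; it is off by default so the unadjusted base score
is the canonical behaviour.

### Combining evidence sources

Each source is scored independently; the final score is the weighted mean
Σ wS / Σ w with weight 1 for human and `mouse_weight` ∈ [0, 1] (default
1.0) for mouse sources, mouse evidence reaching a human candidate only
through a strictly one-to-one ortholog pair (one-to-many rows in the
ortholog table are dropped with a warning — silently guessing among
paralogs would be worse than discarding). Sources without data for a gene
are simply absent from the mean, so a gene probed on one platform only is
still scored. With mouse_weight = 0 and mouse-only evidence the combined
score is undefined and the gene is flagged `no_data`. A weighted mean
(rather than a sum) was chosen so that genes measured in fewer sources are
not systematically penalized; the two differ only by a positive per-gene
factor when source coverage is equal, and mouse_weight = 0 reproduces
human-only rankings rank-for-rank (a tested invariant).

Ranking is competition style (ties share the smaller rank, 1-2-2-4) with
lexicographic gene id as the deterministic display order within ties.

## Identifier resolution

Input tokens resolve through a fixed precedence ladder: approved symbol >
Ensembl > Entrez > RefSeq > alias; symbols and aliases match
case-insensitively, accessions case-sensitively with trailing `.N`
versions stripped. When several genes share a token, the optional
tie-break chooses the unique match that has expression data; beyond that
the token is reported ambiguous — the tool never guesses among equally
supported genes. Tokens failing against the human registry are retried
against the mouse registry and ortholog-converted (human and mouse symbols
typically differ only in case). Variant-to-gene assignment uses the full
gene span (introns included) by default since candidate VCFs are expected
to be pre-filtered for consequence upstream; exon-only overlap is a flag.
Coordinates are 1-based inclusive throughout.

## Benchmarking machinery

A benchmark replicate ranks the disease gene against `size` random decoys
(default sizes 50/100/200/500, 30 replicates, seeded). ROC curves are
built by sweeping every integer rank cutoff, pooling replicates into one
curve; AUC is the trapezoidal area and provably equals the Mann–Whitney
probability that a positive outranks a negative with ties counted ½ — the
package carries both routes and the tests compare them against brute-force
pair counting. Per-replicate AUC averaging is available separately. Rank
summaries use the sample SD (n − 1; flagged undefined for a single
replicate) and the mean reciprocal rank.

The distributional test of the core hypothesis pools, over disease genes,
their z̄_t in affected tissues (sample A) versus all other tissues
(sample B) and applies a one-sided two-sample Kolmogorov–Smirnov test
(asymptotic p-value, via scipy). The direction is an explicit parameter
defaulting to "affected stochastically greater", matching the hypothesis
that disease genes are elevated in affected tissues.

## Synthetic data generator

The generator emulates exactly what the scoring pipeline consumes:
background expression i.i.d. log-normal per (gene, experiment) —
exp(N(μ, σ)) with μ = 1.0, σ = 1.0 log-units by default, matching the
positive, right-skewed character of normalized expression data — across
500 genes, a 10-tissue panel and two experiments per tissue in each of the
four evidence sources. Planted (gene, tissue) signals add their effect
size in log units (multiplicative on the expression scale) in every
experiment of that tissue, so the full z-score pipeline is exercised
rather than injecting z-values directly. 90% of genes receive a one-to-one
mouse ortholog; the gene model places genes in non-overlapping 5 kb spans
(configurable overlap), with unique plus deliberately shared aliases for
resolver tests. An optional per-gene baseline offset
(`gene_baseline_log_sd`, default 0 to keep the background i.i.d.) creates
genes with conserved high/low expression for housekeeping-adjustment
tests. All randomness flows from one seed through independent named
streams, so every artifact is reproducible on its own.

What the generator does **not** emulate: correlated tissue expression
programs, platform-specific artifacts (probe saturation, count
overdispersion), batch effects, or missing-at-random gene dropout beyond
what tests construct explicitly. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under a clean planted-signal
model — not performance on real expression compendia, where cross-tissue
correlation makes discrimination harder.

## Verified behaviour at the shipped problem sizes

The test suite verifies (all sizes chosen as comfortable desk-scale
defaults): the z-transform against independent brute-force evaluation to
1e-12 on 120 random vectors, with affine invariance and order
preservation; base-score collapse (S = Σ z̄ when all ratios are 1) and
strict monotonicity above the median; trapezoid AUC equal to pair-counting
on 100 random rank fixtures; a random-rank classifier pooling 1000
replicates to AUC 0.5 ± 0.02 and a perfect classifier to exactly 1; full
planted-signal recovery — a 3 log-unit single-tissue effect among 50
decoys ranks first in ≥ 95 of 100 seeds (observed 100), while a zero
effect yields a rank distribution indistinguishable from uniform
(chi-square goodness of fit over 1000 seeds, α = 0.01); and rank-for-rank
equality of mouse_weight = 0 with human-only scoring.

## Known limitations

- The log-ratio boost is unbounded as a gene's cross-tissue median
  approaches zero from above; interpret very large scores for
  low-baseline genes with care.
- The asymptotic KS p-value is inaccurate for very small samples; exact
  small-sample p-values are out of scope.
- No genome-build liftover or live identifier services; mapping tables are
  taken as given.
- Raw platform normalization (RMA, TPM, etc.) must happen upstream; inputs
  are assumed normalized per experiment.
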