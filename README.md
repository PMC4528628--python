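# tissuerank

Candidate disease gene prioritization from tissue-specific expression
profiles.

Linkage intervals and exome filtering routinely leave a geneticist with
dozens to hundreds of candidate genes. `tissuerank` orders them by a single
piece of experimental evidence that needs no prior knowledge of the disease
or the genes: *a gene causing a tissue-restricted phenotype tends to be more
highly expressed in the affected tissue(s) than elsewhere*. Because the
score is built from baseline expression measurements rather than
annotations, literature or interaction networks, it carries no bias toward
well-characterized genes and is equally applicable to genes nobody has
studied yet.

## The score

The expression database holds normalized values for many experiments, each
an expression vector over genes for one tissue in one **evidence source**
(human/mouse × microarray/RNA-seq). Within every experiment the values are
robustly standardized to modified z-scores,

    z_e = 0.6745 · (e − Ē) / MAD,        MAD = median |e − Ẽ|,

where Ē and Ẽ are the experiment mean and median (a median-centered variant
is available). For each gene and source, z̄_t is the mean modified z-score
over all experiments of tissue *t*, and z̃ is the median of the z̄_t across
the gene's tissues. Given the user's affected tissue set *T*, the base
score per source is

    S_g = Σ_{t ∈ T}  z̄_t · (1 + ln(z̄_t / z̃))   if z̄_t > 0 and z̃ > 0
                     z̄_t                          otherwise,

rewarding expression elevated above the gene's own cross-tissue baseline
even when absolute levels are modest. Per-source scores are combined as a
weighted mean (human weight 1, mouse weight user-set in [0, 1], transferred
through one-to-one orthologs); candidates are ranked by the combined score
with competition ranking. An optional variance adjustment damps genes that
are ubiquitously high across tissues (housekeeping profiles).

Candidates may be given as a delimited list of symbols/aliases/accessions
(Ensembl, Entrez, RefSeq — mouse identifiers are converted through
orthologs), as genomic regions `chr:start-end`, or as a pre-filtered VCF.
Benchmarking utilities rank a known disease gene against random decoy sets
and report rank-cutoff ROC curves, AUC (equal to the Mann–Whitney
pair-ordering probability), mean rank ± SD and mean reciprocal rank, plus a
one-sided two-sample Kolmogorov–Smirnov test of the elevated-expression
hypothesis.

## Worked example

No real database ships with the package; the built-in generator creates one
with a known, planted signal (here gene `G0001`, 3 log-units high in liver):

```sh
tissuerank simulate --n-genes 60 --planted G0001:liver:3.0 --seed 11 --out-dir demo
printf 'GENE1, GENE7; GENE13\nGENE20 GENE33\n' > demo/candidates.txt
tissuerank prioritize --genes demo/candidates.txt --tissues liver \
    --db demo/expression.tsv --gene-model demo/gene_model.tsv \
    --orthologs demo/orthologs.tsv --out demo/results.tsv
```

`demo/results.tsv` (columns trimmed):

```
rank  gene_id  approved_symbol  combined_score  human_rnaseq  mouse_rnaseq
1     G0001    GENE1            23.9586         22.4193       18.9392
2     G0013    GENE13           -0.144392       -1.90226      -0.657465
3     G0033    GENE33           -0.30791        -0.86921      -0.660423
4     G0020    GENE20           -0.797186       -0.754811     -0.243601
5     G0007    GENE7            -1.25479        -1.66462      -1.23663
```

The planted gene tops the list by two orders of magnitude: its liver z̄ is
far above its own cross-tissue median, so the log-ratio modifier multiplies
an already large z̄; the background genes sit near zero. Benchmarking the
same gene against 30 random decoy sets:

```sh
tissuerank benchmark --disease-gene G0001 --tissues liver \
    --db demo/expression.tsv --orthologs demo/orthologs.tsv \
    --sizes 20,50 --replicates 30 --seed 3 --out-prefix demo/bench
```

```
decoy_size  replicates  auc  mean_rank  sd_rank  mrr
20          30          1    1          0        1
50          30          1    1          0        1
```

An AUC of 1 with mean rank 1 is the perfect-retrieval ceiling — expected
for a signal this strong; weaker planted effects grade the AUC down toward
the random-classifier value of 0.5. Every command writes a JSON manifest
(inputs digests, configuration, seed, version) beside its outputs.

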