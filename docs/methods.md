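# Methods

## Model overview and assumptions

The package estimates regional constraint against aberrant splicing by
comparing observed population variation to a splice-aware mutational
expectation. The core assumptions are:

- **Purifying selection leaves a depletion signature.** If splice-disrupting
  variants at a locus reduce fitness, a large healthy cohort will carry fewer
  variants there than the local mutation rate predicts. The signal lives in
  the contrast between observed and expected counts, not in either alone.
- **Splice relevance is measurable per substitution.** Each possible ref→alt
  substitution carries four delta scores (acceptor gain/loss, donor
  gain/loss) in [0, 1]; their sum in [0, 4] is the site's splice-relevance
  score. For sites without an observed variant the maximum summed score over
  the three possible substitutions is used; for variant sites the variant's
  own substitution score is used, so the matrix asks "how splice-relevant was
  the change that actually occurred".
- **Mutation rate is adequately captured by reference allele × score bin.**
  The expectation model is deliberately coarse: 4 reference alleles × 8
  summed-score bins = 32 cells. Sequence context (e.g. CpG effects) enters
  only through whatever context the upstream splice predictor consumed. A
  trinucleotide mutation model is explicitly out of scope.
- **Autosome and X differ.** Different effective population sizes and
  hemizygosity make substitution rates incomparable across the two, so
  matrices, windows, and normalization maps are kept fully separate. The Y
  chromosome is excluded, as are pseudoautosomal intervals on X.

## The statistic

Per window, with raw tallies `O_raw[i]` (retained variants in cell *i*) and
`E_raw[i]` (sum of per-site substitution probabilities over sites assigned to
cell *i*):

```
O/E = Σ_i X[i] · (O[i] − E[i]) / E[i],   O[i] = 1 + O_raw[i],  E[i] = 1 + E_raw[i]
```

The per-cell pseudocount of 1.0 serves three purposes: empty cells are
well-defined, the null (observed matching expectation everywhere) is exactly
0, and the lower limit is an unbounded negative value rather than the 0 floor
of a ratio statistic — so the constrained tail keeps resolution. More
negative raw values mean stronger constraint; after rank normalization the
most constrained region scores 1.0. One stray sentence in the source
material inverts this direction; the sort rule ("largest to smallest", 1.0 =
most constrained) and the figure legends are unambiguous, and this package
follows them.

Weight schemes (`X[i]`): `unweighted` (1), `linear` (bin midpoint score —
the bin representative is not specified upstream, the midpoint is this
package's choice), `log` (−10·log10 Proportion[i]), `one-minus-proportion`,
`inverse-proportion` (1/Proportion[i], the default and best performer), and
`inverse-substitution-rate` (1/p[i]). Cells with a zero denominator get
weight 0 and a logged warning, so they contribute nothing rather than
exploding.

## Windows and filtering

Merged gene spans are tiled 5′→3′ with non-overlapping 50 bp windows by
default (a smaller step yields overlapping windows; position queries then
take the maximum score over covering windows). A trailing window is clipped
at the gene end. Per-gene mode scores whole genes instead.

Windows are retained only if they have at least 6.5415 informative sites
(summed score > 0) and at least 80 % of their bases scored. The 6.5415
critical value is carried as a named constant taken from an F-distribution
table at α = 0.025; the upstream derivation cites "7 degrees of freedom" for
the 8 proportion bins, which under-specifies an F distribution (it needs two
df parameters), and no (df1, df2) pair we tried reproduces 6.5415 — so the
constant is adopted verbatim rather than recomputed. The window filter also
checks λ·window ≥ cutoff, where λ is the genome-wide fraction of scored
protein-coding sites with summed score > 0 (a Poisson rate for informative
sites per window), and warns when the configured window size cannot be
expected to clear the cutoff; 50 bp is the default minimum window.

Single-exon genes do not splice, so their depletion is not splicing
constraint. Regions inside single-exon genes have their raw O/E shifted in
the positive (tolerant) direction; the default shift moves the single-exon
mean to the 80th percentile of the multi-exon raw O/E distribution (clamped
at ≥ 0). The shift magnitude is openly arbitrary upstream; the percentile
rule is this package's concrete, config-exposed instantiation.

## Input filtering

Population variants are retained iff they are biallelic SNVs (multi-allelic
records are decomposed on load), PASS-filtered, with allele count ≥ 1,
covered (≥10X in ≥50 % of samples where a per-position summary exists;
positions absent from the summary are treated as covered), reference-matching,
inside a merged protein-coding interval, scored for their specific alternate,
outside the repeat mask (segmental duplications/self-chains at ≥95 %
identity), and absent from the truth set (leakage control). The criteria are
applied as a conjunction, so retention is order-independent; per-criterion
discard tallies are reported. Sites used for the expectation obey the same
inclusion rules (scored, in-gene, unmasked, covered, non-PAR), so observed
and expected counts are drawn from the same base population. A site lying in
genes on both strands is counted once.

## ConSpliceML

A RandomForestClassifier with 1000 trees over exactly three features —
regional constraint score, max splice-prediction delta, max
spliceosome-classifier score — in fixed order. Probabilities are the
forest's vote fraction. Hyperparameters beyond tree count are scikit-learn
defaults (unlimited depth, sqrt features per split, bootstrap), with the
seed recorded in the persisted model file for bitwise reproducibility.
Whether the splice-prediction feature should be the max of the four deltas
or their sum is ambiguous upstream; the max is the default here
(`spliceai_feature="max"`), with the sum available as a switch. A CADD-style
comparison score may be carried through reports but is never a model
feature. Only autosomal truth variants carrying all three features are used;
train/test splitting is grouped by constraint region (GroupShuffleSplit),
cross-validation is class-stratified (StratifiedKFold); validation folds
partition the training set, so no region appears in two validation folds.

## Evaluation statistics

Average precision is the step sum Σ(R_i − R_{i−1})·P_i over descending
distinct-score thresholds (no interpolation); the trapezoidal PR area is
reported separately as a clearly labeled secondary because its integration
rule differs. Odds-ratio enrichment per decile uses the four-cell formula
with a 1.96 multiplier on the log-OR standard error (the printed convention,
not `norm.ppf(0.975)`); deciles with any zero cell receive the
Haldane–Anscombe 0.5 correction on all four cells and are flagged in the
output. Decile edges are lower-inclusive with only the final bin closed
above, so 0.1 lands in the second bin and 1.0 in the tenth; the edge lookup
is done by binary search on rounded edges so that values like 0.7 land in
their own bin despite binary floating point.

Relative-position labels (A-1/A-2, D+1/D+2, splice region = 8 intronic + 3
exonic bases, intronic/exonic ≤ 10 bp, deep beyond) are computed strand-aware
against internal exon junctions; the transcription-first exon has no acceptor
and the last no donor, and ties between acceptor and donor distance resolve
to the acceptor side. Every genic base receives exactly one label.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's study conditions: 40 genes (4
exons × ~120 bp, introns ~300 bp, alternating strands), 20 % of genes
constrained, depletion factor d = 0.1 at sites with summed score ≥ 0.5
inside constrained genes, per-reference baseline variant rates A/T = 0.13
and C/G = 0.17 (≈1 SNV per 7 genic bases, a large-cohort-like genic
density), and a 60/240 pathogenic/benign truth set (PR baseline 0.2). Score
tracks peak at exon junctions (canonical bases in [2.5, 4], the splice
region in [0.8, 2.5]) over a background mixture that populates all eight
bins, with ~36 % of background sites above the depletion threshold — enough
expected high-bin variants per 50 bp window (≈2.7) for a single window to
carry a detectable depletion signal at d = 0.1. About 15 % of background
sites carry an exact-zero score (uninformative), 1 % of genic sites are
unscored, 0.5 % fail coverage, and 1 % of variants fail the quality filter,
so every filtering pathway is exercised. Truth variants are withheld from
the population callset.

What passing recovery tests shows: the pipeline can detect ten-fold
depletion of splice-relevant variation in 50 bp windows at realistic variant
densities, and the detection degrades smoothly as depletion vanishes. What
it does not show: performance on real genomes, where splice scores are far
sparser at high values, mutation rates are context-dependent, genes overlap,
and pathogenic/benign truth labels are noisy. The generator's high-score
background fraction is deliberately larger than reality so that desk-scale
windows contain signal; real constraint modeling relies on population-scale
cohorts instead.

## Numerical choices and degenerate inputs

- Summed scores live in [0, 4]; bin edges default to
  [0, .1, .2, .4, .6, .8, 1, 2, 4] (the upstream source shows 8 bins but
  never prints the edges; any 8-bin partition of [0, 4] is accepted, and the
  splicing-unaware control model is the single-bin [0, 4] + unweighted
  case). The last bin is closed so 4.0 is binned.
- Empty matrix cells get p = 0 with a flag rather than smoothing; the O/E
  pseudocounts absorb the degeneracy downstream.
- Rank normalization uses average ranks for ties; it requires ≥ 2 regions.
- A site carrying several retained alternates is counted once in the matrix
  (at the largest variant-specific sum) while each variant counts in the
  window's observed tally.
- Internal coordinates are 0-based half-open; VCF/GTF/TSV are converted at
  the I/O boundary; BED is native.
- `log_display_score` caps at 60 (score 1.0 would be −10·log10(0) = ∞).

## Known limitations

- The expectation model ignores local sequence context beyond what the
  splice predictor saw; regional mutation-rate variation (replication
  timing, methylation) is unmodeled.
- The 6.5415 informative-site cutoff is inherited, not derived; treat it as
  a calibrated constant.
- Desk-scale synthetic recovery (AUC ≈ 0.85 at d = 0.1) reflects the
  generator's conditions, not clinical performance.
- No liftover, no indels or structural variants, no per-tissue modeling.
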