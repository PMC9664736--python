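# consplice

Regional splicing-constraint modeling and ensemble prioritization of
deleterious splice-altering variants.

Roughly half of rare-disease cases remain undiagnosed after genome
sequencing, and variants that disrupt splicing from intronic or exonic
positions outside the canonical donor/acceptor dinucleotides are a major
blind spot. Splice-prediction networks estimate whether a variant *alters*
splicing; they do not say whether altered splicing at that locus would be
*deleterious*. This package measures that second quantity as genetic
constraint: genomic regions where a healthy population carries far fewer
splice-relevant variants than a mutational model expects are inferred to be
under purifying selection against aberrant splicing.

## The model

Every position in merged protein-coding genes is assigned a summed splice
score, `sum(AG, AL, DG, DL)` over the four per-substitution delta scores
(acceptor gain/loss, donor gain/loss). Sites are tallied by reference allele
and one of eight summed-score bins into a 4 × 8 substitution matrix of
variant-bearing vs. variant-free sites, giving 32 per-site substitution
probabilities `p(ref, bin)` and genome-wide cell proportions
`Proportion[i]` (autosome and X are modeled separately; the Y chromosome
and pseudoautosomal regions are excluded).

Genes are tiled into 50 bp windows. Each window accumulates observed
retained-variant counts `O_raw[i]` and expected counts
`E_raw[i] = Σ p(ref, bin)` over its sites, and is scored with the
likelihood-weighted observed/expected statistic

```
        32
O/E  =  Σ   X[i] · (O[i] − E[i]) / E[i],    O[i] = 1 + O_raw[i],  E[i] = 1 + E_raw[i]
       i=1
```

with `X[i] = 1/Proportion[i]` by default (five alternative weighting schemes
are provided). The pseudocounts center the null at 0 and leave the statistic
unbounded below, so stronger constraint is more negative. Windows with fewer
than 6.5415 informative sites (summed score > 0) or with less than 80 % of
their bases scored are dropped, and the remaining raw values are
rank-normalized to a constraint score in [0, 1], with 1.0 the most
constrained region.

Because regional scores are not per-nucleotide predictions, the package also
provides **ConSpliceML**: a 1000-tree Random Forest over the feature vector
[regional constraint, max splice-prediction delta, max spliceosome-classifier
score] that outputs the probability a variant is a pathogenic splice-altering
variant (recommended preliminary cutoff: 0.5). Training uses a 60/40 split
grouped by constraint region — no region contributes variants to both sides —
and class-stratified 5-fold cross-validation.

Evaluation utilities implement precision–recall curves with the step-sum
average precision `Σ (R_i − R_{i−1}) P_i`, the analytic PR baseline
`P/(P+B)`, decile binning (lower edges inclusive; the last bin closed), and
per-decile odds-ratio enrichment `OR_i = (A_i/B_i)/(C_i/D_i)` with
`s.e. = sqrt(1/A + 1/B + 1/C + 1/D)` and 95 % CI `exp(ln OR ± 1.96·s.e.)`.

A synthetic-data generator produces desk-scale genomes (genes on both
strands, junction-peaked score tracks, population variants with tunable
depletion `d` at high-score sites of constrained genes, leakage-controlled
truth sets) so the entire pipeline is testable without population-scale
downloads.

## Worked example

```python
from sklearn.metrics import roc_auc_score
from consplice import (
    simulate_bundle, fit_from_bundle, ground_truth_labels,
    assemble_examples, group_split, ConSpliceML, pr_curve, average_precision,
)

bundle = simulate_bundle(seed=7)              # 40 genes, 20% constrained, d=0.1
model, tally = fit_from_bundle(bundle)        # filter -> matrix -> windows -> scores
regions = model.to_frame()
print("regions retained:", len(regions))

gt = ground_truth_labels(bundle, model.all_regions())
frame = regions.merge(gt, on="region_id")
med = frame.groupby("constrained")["constraint_score"].median()
print("median score constrained: %.3f  tolerant: %.3f" % (med[True], med[False]))
print("recovery AUC: %.3f" % roc_auc_score(frame["constrained"], frame["constraint_score"]))

examples = assemble_examples(bundle.truth, model, bundle.genome)
train, test = group_split(examples, 0.6, seed=7)
clf = ConSpliceML(n_trees=1000, random_state=7).fit(train, train["label"])
curve = pr_curve(clf.predict_pathogenic(test), test["label"])
print("test examples: %d (baseline %.3f)" % (len(test), curve.baseline))
print("average precision: %.3f" % average_precision(curve))
```

prints

```
regions retained: 1124
median score constrained: 0.822  tolerant: 0.406
recovery AUC: 0.851
test examples: 124 (baseline 0.153)
average precision: 0.924
```

The constrained genes — where the simulator depleted splice-relevant
variation ten-fold — receive visibly higher constraint scores than tolerant
genes (0.82 vs. 0.41 median), the window-level recovery AUC is 0.85, and the
ensemble separates planted pathogenic from benign variants far above the
random-chance precision of 0.153.

The same pipeline is scriptable from the shell:

```bash
consplice simulate --out bundle --seed 7
consplice score-regions --genes bundle/genes.gtf --scores bundle/site_scores.tsv \
    --variants bundle/population.vcf --reference bundle/reference.fa \
    --mask bundle/mask.bed --coverage bundle/coverage.tsv --truth bundle/truth.tsv \
    --out model
consplice train --truth bundle/truth.tsv --regions model/constraint_regions.tsv --out trained
consplice predict --model trained/consplice_ml.joblib --examples trained/test_set.tsv --out preds.tsv
consplice evaluate --predictions preds.tsv --out eval
```

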