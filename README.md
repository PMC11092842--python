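# cnvsig

A workbench for classifying the **clinical significance of copy-number
variants (CNVs)** — deletions and duplications of at least 50 bp — into the
three classes used in clinical genomics: *benign*, *VUS* (variant of
uncertain significance) and *pathogenic*. It is aimed at genomic researchers
and method developers who want a transparent, retrainable, explainable
multi-class CNV classifier and a reproducible harness for benchmarking it
against other tools.

## What it does

For each CNV the package computes a fixed panel of 17 genomic features in
six groups:

| group | features |
|---|---|
| genomic position | centromere distance, telomere distance |
| composition | GC content, bp length |
| functional annotation | counts of overlapping genes, gene-linked diseases, exons (±10 bp splice padding), promoters (1,000 bp upstream of each TSS), pathogenic SNVs/indels |
| population frequency | popmax allele frequency among type-matched SV records with ≥ 50 % reciprocal overlap |
| conservation | max of a centred moving average of per-base PhyloP and phastCons scores |
| dosage sensitivity | one-hot haploinsufficiency (HI) and triplosensitivity (TS) evidence-category counts, min HI index, max pLI, min LOEUF |

Count features and bp length are mapped through `x → ln(1+x)` and every
feature is min–max scaled with statistics fitted on training rows only.

Separate multi-class models are trained for deletions and duplications.
Training is a seeded, stratified 5-fold protocol: (1) rank a roster of
common scikit-learn architectures by mean macro F1; (2) randomized
hyperparameter search for the winner; (3) isotonic calibration of the final
estimator's probabilities (per-class one-vs-rest maps learned out-of-fold,
renormalized to the simplex). Prediction returns
`(Pr(benign), Pr(VUS), Pr(pathogenic))` plus the argmax label, with ties
broken conservatively (pathogenic > VUS > benign).

Predictions are explained with exact Shapley values (interventional
tree-Shapley for tree models, a permutation estimator otherwise), exported
as beeswarm and per-variant force plots, each with a machine-readable TSV
twin. A benchmarking module computes one-vs-rest PR/ROC curves and AUCs,
complement scores (`1 − Pr(pathogenic)`) for single-score tools, macro F1,
accuracy and confusion matrices.

Everything is testable offline: a synthetic-fixture generator emits a
complete annotation bundle (genome FASTA, gene models, disease map,
pathogenic SNVs, SV frequencies, conservation tracks, dosage regions,
chromosome structure) plus CNV sets whose labels follow a known generative
rule, so the whole pipeline can be validated without external downloads.

## Worked example

```sh
cnv-workbench simulate --seed 3 --cnv-seed 5 --out fx          # training fixture
cnv-workbench simulate --seed 3 --cnv-seed 6 --out fx_test     # disjoint test CNVs
cnv-workbench annotate --cnvs fx/cnvs.tsv --bundle fx/bundle.yaml --out features.tsv
cnv-workbench train --features features.tsv --cnv-type DEL --folds 5 --draws 25 \
    --seed 13 --roster random_forest,logistic_regression,decision_tree --out model_DEL
cnv-workbench train --features features.tsv --cnv-type DUP --folds 5 --draws 25 \
    --seed 13 --roster random_forest,logistic_regression,decision_tree --out model_DUP
cnv-workbench predict --model model_DEL --model model_DUP \
    --cnvs fx_test/cnvs.tsv --bundle fx/bundle.yaml --out preds.tsv
```

`preds.tsv` holds the three calibrated probabilities and the label per CNV:

```
id	cnv_type	pr_benign	pr_vus	pr_pathogenic	label
cnv_00001	DUP	1	0	0	benign
cnv_00002	DEL	1	0	0	benign
```

Benchmarking those predictions against the fixture's labels
(`cnv-workbench benchmark --truth truth.tsv --scores workbench=preds.tsv
--out report.json`) prints `macro_f1 1.0, accuracy 1.0` with PR and ROC AUC
of 1.0 in every class — the fixture's labels are a deterministic function of
in-panel features, so a correctly wired pipeline recovers them exactly.
Shapley exports come from
`cnv-workbench explain --model model_DEL --cnvs fx_test/cnvs.tsv
--bundle fx/bundle.yaml --class pathogenic --beeswarm bee.png
--per-variant cnv_00002:force.png`; `bee.tsv` ranks features by mean
absolute attribution (the dosage HI-category-3 count ranks first for the
deletion model, as the generative rule dictates).

Real annotation resources plug in the same way: point `bundle.yaml` at your
own gene models, conservation tracks, SV frequency and dosage tables, and
feed curated variant tables through `cnv-workbench curate`.

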