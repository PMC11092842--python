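# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open (BED convention): an
interval `[start, end)` covers `end − start` bases and abutting intervals do
not overlap, matching the bedtools default. VCF input (1-based, inclusive,
with an `END` tag) is converted at the reader boundary; chromosome names are
normalized by stripping a leading `chr` and uppercasing X/Y/MT, since
resource files mix dialects. Overlap queries are served by per-chromosome
interval trees; a query returns every stored interval sharing at least one
base with the probe, ordered by (start, end, insertion), and is validated
against a naive all-pairs scan in the test suite.

## Feature panel

**Genomic position.** The centromere distance takes the CNV boundary nearest
the centromere (end coordinate on the P arm, start coordinate on the Q arm);
the telomere distance takes the boundary furthest from it. Arm membership is
decided by the CNV midpoint. A CNV whose midpoint falls inside the
centromere — a case the per-arm formulas do not define — gets centromere
distance 0 and the smaller of the two arm telomere distances; all distances
clamp at 0.

**Composition.** GC content counts G and C over called bases (ACGT,
case-insensitive, so soft-masking cannot change the value); N bases are
excluded from the denominator and an all-N interval yields 0 with a warning.
Length is simply `end − start`.

**Functional annotation.** Gene, exon, promoter and pathogenic-SNV counts
use a 1 bp minimum overlap. Exons are padded by ±10 bp to include canonical
splice regions before counting, and exons are summed across all genes.
Promoters are the 1,000 bp immediately upstream of each transcription start
site on the gene's strand. The disease count sums, over every overlapping
gene, the number of diseases linked to that gene *without* deduplicating
diseases shared between genes — summation distinguishes multi-gene hits,
which is the quantity the classifier should see; this is a deliberate
resolution of an ambiguity in how "total diseases associated with the
gene(s)" could be read.

**Population frequency.** The popmax feature is the highest allele frequency
across all populations of all records that match the CNV's type (deletion vs
duplication) and reach ≥ 50 % reciprocal overlap — `min(o/len(a), o/len(b))`
with `o` the shared bases — and 0 when no record qualifies.

**Conservation.** Raw single-base PhyloP/phastCons scores are volatile, so
the per-base track is smoothed with a centred moving average before taking
the maximum inside the CNV: for each base `p` in the CNV, the smoothed value
is the mean of the raw scores present within a `w`-base window centred on
`p`, with uncovered bases excluded from the mean (windows never contribute
phantom zeros). The window defaults to 1,001 bp — wide enough to decorrelate
the maximum from CNV size at desk scale while preserving exon-level bumps —
and is configurable; `w = 1` reduces exactly to the raw in-interval maximum,
which the tests exploit as an identity check. Maxima are taken over window
centres strictly inside the CNV. When no score exists within the CNV plus
half a window, a configurable sentinel (default 0) is returned with a
warning.

**Dosage sensitivity.** HI and TS evidence categories (default vocabulary
`{0, 1, 2, 3, 30, 40, not_evaluated}`, extensible because curation dialects
vary) are one-hot encoded and *summed* across all overlapping curated
regions, so two overlapping regions with HI category 3 yield `hi_3 = 2`. The
scalar metrics take the extreme in the intolerant direction: minimum HI
index, maximum pLI, minimum LOEUF over regions where the metric is curated.
When nothing overlaps (or nothing is curated) each metric falls back to a
sentinel at its loss-*tolerant* extreme — HI index 100, pLI 0, LOEUF 2.0 —
so absence of evidence reads as tolerance rather than as intolerance; all
three are configurable.

**Transform.** The six right-skewed count features (genes, diseases, exons,
promoters, pathogenic SNVs, bp length) are mapped through `ln(1 + x)`, which
is well-defined at zero counts. Every feature is then min–max scaled with
statistics fitted on training rows only; transformed values are clamped to
[0, 1] at prediction time so behaviour outside the training range is defined
and no test-set information leaks into the scaler. A constant training
column maps to 0.

## Dataset curation

Submitted significance labels collapse with a pathogenic-dominant rule: any
pathogenic/likely-pathogenic designation ⇒ pathogenic; otherwise any VUS ⇒
VUS; only benign/likely-benign ⇒ benign; anything else (drug response, risk
factor, …) is ambiguous and dropped. Filters then apply in a fixed order:
non-DEL/DUP types, ambiguous labels, coordinate duplicates (keep one when
collapsed labels agree, drop all on conflict), sub-50 bp records, and — for
test sets — records whose exact `(chrom, start, end, type)` key matches a
training submission (leakage guard). The duplicate key deliberately includes
the CNV type so a deletion is never merged with a co-located duplication.
The report satisfies `input = retained + Σ removed` by construction and
curation is idempotent.

## Training, calibration, prediction

Deletions and duplications get independent models. Stage 1 ranks a
configurable architecture roster (eight common scikit-learn classifiers by
default; the selection machinery, not the roster census, is the contract) by
mean macro F1 under seeded stratified 5-fold cross-validation; stratification
guarantees every class appears in every fold and requires at least `k`
members per class. Stage 2 draws `n` hyperparameter settings (spaces shipped
in `cnvsig/data/hyperparameter_spaces.yaml`) with a seeded sampler and keeps
the best CV score, ties resolved by draw order. Stage 3 fits the final
estimator on all training rows and calibrates it with per-class isotonic
regressions learned on out-of-fold predictions (one-vs-rest), renormalizing
the calibrated scores to the probability simplex. Whether calibration should
be one-vs-rest or multinomial is genuinely open; one-vs-rest plus
renormalization matches the standard calibration wrapper this protocol is
built on. The label is the probability argmax with a clinically conservative
tie-break: pathogenic > VUS > benign.

Tests and the acceptance script run the protocol at desk scale — a
3-architecture roster, 25 draws, 5 folds, 300 training CNVs per fixture —
which recovers the synthetic generative rule with macro F1 ≥ 0.95; the
full-scale knobs (roster size, 10,000 draws) are plain parameters.

## Shapley attributions

Attributions explain the *pre-calibration* estimator on transformer-scaled
features: the isotonic maps are monotone per class, so feature influence
directions are preserved, and the uncalibrated estimator is the object the
attribution algorithms treat exactly. For decision trees and averaging
forests the interventional Shapley values are computed exactly: for a
foreground row x and background row z, the coalition game "features in S
take x's values, the rest z's" decomposes over tree leaves into conjunction
games with closed-form Shapley values; summing over reachable leaves and
averaging over a background sample (default 64 rows, seeded) yields
attributions satisfying local accuracy — base value plus attribution sum
equals the model output — to floating-point precision. For arbitrary models
a permutation estimator walks feature orderings (all `d!` of them when
enumerable, otherwise seeded antithetic samples); each walked permutation
telescopes to `f(x) − f(z)`, so local accuracy holds in both modes. Beeswarm
and force plots are static images, each written beside a TSV twin holding
every plotted value so downstream checks never parse pixels.

## Evaluation

One-vs-rest curves rank CNVs by the positive class's score. ROC AUC is
trapezoidal (equal to the Mann–Whitney pair statistic, tested against a
pair-counting oracle); PR AUC uses the step-wise average-precision
estimator, avoiding the optimism of linear interpolation in PR space. Tied
scores collapse into single threshold steps. Tools emitting a single
pathogenicity score get a benign score as its complement `1 − s`; tools with
5-level labels are harmonized (likely pathogenic → pathogenic, likely benign
→ benign); tools without continuous scores are excluded from curve metrics
and compared only on multi-class summaries (per-class F1, unweighted macro
F1, accuracy, raw and row-normalized confusion matrices).

## Synthetic fixtures

The generator emulates the annotation resources the pipeline consumes, at
desk scale: a few megabase-scale chromosomes with sinusoidally varying GC,
stranded multi-exon gene models laid out on per-arm grids (with a capacity
check), a disease map, pathogenic SNVs clustered inside haploinsufficient
regions, SV frequency records including a set of short, intergenic, common
records, conservation tracks with bumps over exons, a ClinGen-style dosage
table and a chromosome-structure table. CNV labels follow a deterministic
rule over in-panel features only — pathogenic iff the CNV hits an HI-3
dosage region or spans ≥ 8 exons at popmax < 0.01; benign iff < 2,000 bp,
popmax ≥ 0.01 and exon-free; VUS otherwise — so that pipeline recovery is a
meaningful end-to-end check. Observed labels are optionally flipped with
probability ε (the pre-noise rule label stays in the manifest as ground
truth). Bundle and CNV generation take independent seeds so train/test sets
share annotations but not variants; output is byte-identical for fixed
seeds.

What the fixtures do *not* emulate: human-genome scale, realistic
allele-frequency spectra, breakpoint uncertainty, correlated annotation
errors, and label heterogeneity across submitters. Passing the recovery test
therefore demonstrates that the machinery is wired correctly — features
computed as specified, models able to learn a rule expressed in those
features — not that the classifier generalizes to real clinical call sets.

## Numerical and degenerate-input choices

Moving averages use cumulative sums (float64); exact agreement with the
brute-force oracle is asserted to ~1e-9 relative. Probability vectors are
renormalized after calibration and asserted to sum to 1 within 1e-9.
Prediction ties break by fixed class priority; hyperparameter-score ties by
draw order; index-query ties by (start, end, insertion). Empty CNV lists
produce empty matrices with full headers; an empty evaluation input, a
single-class truth vector, or a class smaller than the fold count raise
informative errors rather than returning undefined metrics.

## Known limitations

Exact tree attribution scales with trees × background × reachable leaves and
is intended for desk-scale audits, not millions of variants. bigWig
conservation input is out of scope (text bedGraph/wiggle only). The
comparator harness ingests other tools' scores; it never runs the tools.
Models are serialized with pickle inside a JSON-metadata bundle and should
only be loaded from trusted sources.
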