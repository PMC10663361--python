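# Methods

## The priming model

A cis-regulatory element is *primed* at the stage transition S1 → S2 when it
is already open and reporter-active while its target gene is still silent,
and the gene is then induced at S2. Operationally the classifier emits an
element × transition × gene record iff:

1. the element's distance to the nearest TSS is **strictly greater than
   1,500 bp** (distance from the nearest element edge; 0 if a TSS falls
   inside the element);
2. the element is **enhancer-positive at both S1 and S2** — at least one
   retained screen fragment overlaps it at each stage;
3. the linked gene is **not expressed at S1** — mean CPM across the stage's
   replicates below 9;
4. the gene is **induced at S2** — log2 fold change ≥ 1 (inclusive: exactly
   twofold passes) with BH-adjusted p < 0.05 (strict: padj = 0.05 fails).

Coordinates are 0-based half-open throughout (BED convention); two intervals
overlap iff they share at least one base, so abutting intervals do not
overlap.

### Cross-stage element identity

Peak calls differ slightly between stages, so "active at both stages" needs
a stage-independent element. Stage peaks are merged by single-linkage ≥ 1 bp
overlap into *reference elements*; an element is positive at a stage iff any
constituent peak is, and its fragment counts are the sums over constituent
peaks. The alternative — requiring coordinate-identical peak calls — would
make the both-stages criterion depend on peak-caller jitter.

### Peak-to-gene linking

Promoter-capture Hi-C links take precedence: if any interaction's other end
overlaps the element, the bait gene of the highest-scoring such interaction
is used (missing scores rank lowest; score ties break to the
lexicographically smallest gene id). Otherwise the nearest gene by TSS
distance is used, with the same lexicographic tie-break. Elements on
chromosomes with no annotated gene are dropped with a logged warning.

## Screen activity calling

Screen fragments pass three filters, in order: (a) removal of fragments
coordinate-identical to a negative-control fragment, (b) retention only of
fragments coordinate-identical to a plasmid-library fragment, (c) retention
only of fragments overlapping ≥ 1 ATAC peak. "Identical" is exact
chrom/start/end equality (a slop parameter, default 0 bp, relaxes this).
An empty plasmid library is a hard error because filter (b) would silently
erase everything.

A peak is enhancer-positive with ≥ 1 overlapping retained fragment. Positive
peaks get a state from library-normalised counts
(`norm = 1e6·n/library_total`, fragments per million): High iff
`norm_high > activity_ratio · norm_low` with `activity_ratio = 1.0` by
default. The exact ratio cutoff is not a published constant, hence a
parameter. Exact ties are assigned Low, biasing against over-calling strong
enhancers.

## Expression statistics

* **CPM**: `1e6 · count / column_sum`; zero library sizes are errors.
* **Expressed**: mean CPM across a stage's replicates ≥ 9. The aggregation
  rule is configurable (`mean` | `all`); the mean is the default because the
  per-replicate rule makes the call depend on replicate count.
* **Internal DE fallback**: Welch t-test on log2(CPM + 0.5) per gene with BH
  adjustment across genes; log2FC from stage-mean CPM with the same 0.5
  pseudo-CPM. Genes with zero variance in both stages get p = 1 when means
  are equal (p = 0 otherwise). This is a deliberately simple, documented
  stand-in for a proper count-model DE; externally computed DE tables
  (gene_id, stage1, stage2, log2fc, pvalue, padj) take precedence whenever
  supplied, and the fallback refuses to run with fewer than two replicates
  per stage.
* **Bonferroni**: `min(1, p·m)` with a caller-chosen family size m, used for
  the VEGF gene report.

## Expression Z-scores

Per gene: the per-stage mean of log2(CPM + 0.5) over replicates is
standardised across the stage axis (population moments: mean 0, sd 1 with
ddof = 0). Genes constant across stages contribute all-zero profiles rather
than NaNs. The per-stage median over the gene set is reported. eRNA
summaries at intergenic primed elements use the same transform on
CPM-normalised per-element tag counts, normalising against the full stage
library (not the subset being summarised). The +0.5 pseudo-CPM makes
invariance to uniform library rescaling approximate at finite counts and
exact only in the deep-coverage limit.

## Motif scanning

Log-odds scores in bits against a background base distribution (uniform by
default, configurable). Matrix probabilities are floored at 1e-3 and each
position renormalised before logging, so zero counts never give −∞ and a
certain base scores ≈ 1.996 bits, not 2. Both strands are scanned; reverse
hits are reported at the forward-coordinate window start. N bases score 0
(background). Per-motif thresholds default to **0.80 × the maximum
achievable score** — the original analyses relied on a scanner's internal
thresholds, which are not published constants, so the fraction-of-maximum
convention keeps the cutoff explicit and reproducible.

## The priming network

Nodes are TF families (all motifs sharing a family label collapse) and
primed target genes. Edge F → G iff a motif of family F hits a primed
element linked to G **and** at least one member gene of F is expressed at
S1, using the same CPM ≥ 9 threshold as the gene gate (the TF-expression
cutoff for network membership is not separately published; harmonising the
two avoids a free parameter). Family nodes carry the maximum member-gene
stage-mean CPM as their expression attribute. Rebuilding the network with
S2 expression and diffing edge sets reports motif-usage changes upon
activation. Exports: SIF, node-attribute TSV, GraphML, all sorted and
byte-stable.

## Feature comparison

Elements of a transition are labelled *primed* (classifier output) or
*active_enhancer* (distal, positive at both stages, linked gene expressed at
S1 — the natural contrast class). The binary matrix has one column per
ChIP/histone peak set (1 iff ≥ 1 bp overlap) plus the motif-presence
columns. Per class, feature percentages are column means × 100; the
primed-class percentages are regressed on the active-class percentages by
OLS (one point per feature), reporting slope, intercept, R² and the
two-sided slope p-value (t statistic, n − 2 df).

## VEGF responsiveness

A primed element (of the final transition) is VEGF-responsive iff it
overlaps a peak in the minus-VEGF condition set and no peak in the
all-cytokines set — the direction in which VEGF withdrawal opens the
element and primes the hematopoietic fate. The test is pure overlap against
the supplied condition peak sets; no signal-strength re-calling. Linked
genes get a condition fold change (ratio of replicate means, −VEGF over
+VEGF) and a Bonferroni-corrected Welch p (or externally supplied p-values).

## The synthetic world

The generator emulates the complete input bundle with planted truth. Layout:
one gene locus per 20 kb (body 5 kb, TSS at the 5′ edge); an element sits
8 kb (intergenic) or 3 kb (intragenic) downstream of its host TSS, so every
element is distal by construction and its nearest gene is its host. Defaults:

| parameter | default | rationale |
|---|---|---|
| seed | 7 | single global seed; same seed ⇒ byte-identical bundle |
| n_elements / n_genes | 400 / 1,000 | hundreds of elements, matching the scale of the real screens |
| primed_fraction | 0.1 | 40 planted primed pairs per transition |
| stages | ES, HB, HE, HP | HE stands for the HE1 dataset |
| replicates | 4 | common bulk design; gives the t-test fallback usable df |
| library_size | 20 M reads | keeps per-gene depth at real-data levels despite the ~20× scaled-down gene catalog (a CPM-2 gene has ~40 counts, not 2) |
| dispersion | 0.05 | NB var = μ + 0.05 μ²; typical bulk biological CV ≈ 22% |
| primed_low_cpm / fold | (2, 5) / 16× | silent (CPM < 9) at S1, strongly induced at S2; genes crossing from silent to expressed are typically strongly induced; config enforces only the ≥ 2-fold floor |
| fragment_depth | 20 per positive element-stage | state recovery reliable but not trivial (a High element mis-sorts with probability ≈ 0.3%) |
| high_fragment_prob | 0.8 | sorted libraries at 4:1 / 1:4 high:low for true High/Low elements |
| artefact_rate | 0.05 | screen fragments absent from the plasmid library |
| negative_contamination_rate | 0.02 | screen fragments also present in negative controls |
| chic_fraction | 0.5 | half the elements get a CHi-C link; the rest exercise the nearest-gene fallback |
| vegf_responsive_fraction | 0.5 | of final-transition primed elements |
| persistence_prob | 0.7 | chance a primed element stays open at each stage after activation |

Counts are negative binomial around per-stage CPM targets. Planted genes
(element hosts and TF-catalog members) keep their stated absolute CPM; only
background genes are rescaled so every stage column sums to exactly 1e6 —
a whole-column rescale would silently move planted genes across the CPM-9
line. TF-catalog member genes never host elements for the same reason.
`noiseless=True` replaces NB draws with rounded means, splits sorted
fragments at exact proportions and disables artefacts/contamination.

**What a green test establishes — and what it does not.** The generator
plants clean block structure: elements never overlap each other, every
element is distal, CHi-C links always point at the host gene, and motif
consensi are embedded verbatim. Recovery of the planted truth therefore
verifies the *logic* of the filters, gates and network construction, not
robustness to the messiness of real data (overlapping peaks, ambiguous
linking, partial motif matches, batch effects, count-model misspecification).
The published headline numbers (e.g. 330/294/237 primed elements, 60/80/100%
persistence) derive from deposited sequencing data and are not reproduced at
desk scale.

## Numerical conventions

* Nearest-gene and CHi-C ties break lexicographically by gene id; activity
  ties assign Low; merge order is (chrom, start).
* Writers emit sorted records with numbers at 6 significant digits; the run
  summary JSON is rounded the same way, so identical inputs give
  byte-identical outputs.
* The pipeline records a manifest (package version, parameters, SHA-256 of
  every input); a stage failure aborts naming the stage and leaves a FAILED
  marker beside the partial outputs. Stage outputs are cheap to recompute at
  desk scale, so no result caching is attempted.
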