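# Methods

`k27shared` implements the comparative analyses used to relate H3K27M
diffuse midline gliomas (DMGs) and posterior fossa group A (PFA)
ependymomas through their chromatin and expression landscapes. Both tumor
types suppress PRC2 (via the H3K27M oncohistone or EZHIP overexpression)
and globally lose the repressive H3K27me3 mark; the analyses in this
package characterize what is *kept*: consensus H3K27me3-retained genes,
shared H3K27ac super enhancers, the expression heterogeneity of retained
genes, their activity in single-cell data, and the cohort-level
copy-number and survival context.

## Consensus H3K27me3-retained gene calling

Inputs are per-sample H3K27me3 peak intervals (BED, 0-based half-open) and
a single-interval-per-gene annotation. Each gene gets a promoter window of
`promoter_bp` (default 2,000 bp) immediately upstream of the TSS —
`[tx_start − w, tx_start)` on the `+` strand, `[tx_end, tx_end + w)` on
`−` — truncated at coordinate 0 with a warning. A sample *supports* a gene
if at least one of its peaks overlaps the gene body or promoter by any
base pair (support is binary per sample; peak counts do not matter). A
gene is *retained* in a cohort when its support strictly exceeds the
consensus fraction (default 2/3): the threshold is
`floor(fraction·n) + 1`, giving 7 of 9 and 5 of 6 for the two cohort sizes
this workflow was designed around. Per-cohort retained sets are then
partitioned into shared and subtype-specific genes.

Conventions: abutting intervals do not overlap (strict half-open
intersection, bedtools default); chromosome names are compared verbatim;
gene lists are emitted in lexicographic order for determinism. The
annotation is treated as one interval per gene id; overlapping annotations
(e.g. HOX clusters) are scored independently, with no de-duplication.

## Super-enhancer calling and reciprocal sharing

H3K27ac peaks carrying signal scores are stitched transitively whenever
same-chromosome gaps are ≤ `gap_bp` (default 12,500 bp, the standard ROSE
stitching distance; no TSS-exclusion zone). Stitched signal is the sum of
constituent scores. Candidates are ranked by ascending signal and the
super-enhancer cutoff is a discrete tangent rule: with ranks scaled as
`x_i = (i+1)/n` and signals as `y_i = s_i/max(s)`, the cutoff sits after
the first consecutive pair whose slope `(y_{i+1} − y_i)/(x_{i+1} − x_i)`
exceeds 1; a slope of exactly 1 does not yet qualify, so a perfectly
linear curve yields an empty super set. This scaling is the one choice of
unit-axes normalization under which the two-point case behaves sensibly (a
2-enhancer input with a dominant signal calls that enhancer super); min–max
scaling of the signal axis would force slope ≡ 1 at n = 2 and could never
call anything. The partition is invariant to rescaling all signals by a
positive constant.

An enhancer specific to one tumor type is *promoted to shared* when it
overlaps (any bp) a **called super enhancer** in at least one sample of
the other cohort; overlap with a merely stitched, sub-threshold enhancer
does not promote. Requiring SE status on the other-cohort side is a design
choice: the reciprocal check is defined in terms of rank-ordered super
enhancers, and a weaker any-enhancer criterion would promote on background
acetylation. Enhancers map to genes by nearest TSS from the enhancer
midpoint, ties broken lexicographically.

## Bulk-expression statistics

Differential expression is a row-wise two-sided Student's t with pooled
variance (a Welch flag exists but is off by default, matching the plain
"t test" convention), Benjamini–Hochberg correction across all tested
rows, and the signed ranking metric `(−log10 q) × Δ` where Δ is the
difference of group means in log2 units. q-values of exactly 0 are clamped
to 1e−300 so the ranking stays finite and order-preserving. Zero-variance
rows get p = 1 when means agree and a `degenerate` flag with p = 0 when
they differ.

GSEA-preranked walks the descending ranking (ties broken by gene id);
hits increment the running sum proportionally to `|score|^weight`
(weight 1 by default), misses decrement uniformly, and the enrichment
score ES is the signed maximum deviation. Significance uses gene-label
permutations — random same-size sets from the universe — with
`NES = ES / mean(|permuted ES| of matching sign)` (meandiv) and the
permutation p-value `(r+1)/(m+1)` over same-sign permutations, which is
uniform under the null by exchangeability. Set-size gates default to
15–500 and are overridable so toy universes can be scored. Default 1,000
permutations, seeded.

Probes collapse to genes by keeping the probe with the highest mean over a
reference cohort's samples (ties: lexicographically smallest probe id).
Heterogeneity is the per-gene sample standard deviation (n−1 denominator)
in each cohort, restricted to genes present in both matrices; missing
genes are listed, not silently dropped. Bimodal expression (the
HOXA2-like pattern) is split at the local density minimum between the two
highest modes of a Gaussian KDE (Silverman bandwidth by default,
fixed-bandwidth override available; 512-point grid over the data range);
unimodal densities return no threshold. The package returns a single
threshold value rather than an asymmetric high/low pair of cutoffs.
Mean splits label samples high when strictly above the mean; co-expression
is the per-gene difference of high/low means. Simple ordinary
least-squares fits report slope, intercept and R².

## Single-cell signature scoring

Two per-cell scores for a gene signature:

* **Mean module score** — the arithmetic mean of the signature genes'
  expression values in the cell; signature genes absent from the matrix
  are dropped with a warning. A bin-matched, control-subtracted variant
  was considered and deliberately left out of the default path: the plain
  mean is what the per-cell-type comparisons here are defined on, and the
  Kruskal–Wallis comparison is rank-based, so a monotone per-cell control
  adjustment would not change the planted-recovery conclusions.
* **AUC recovery score** — AUCell-style: genes are ranked per cell by
  descending expression (ties broken lexicographically for determinism),
  the recovery curve counts cumulative signature hits over the top
  `ceil(top_fraction × n_genes)` ranks (default 5%, the AUCell default),
  and the score is the area under that curve normalized to the maximum
  achievable area, hence in [0, 1] and invariant to monotone transforms of
  a cell's values.

Scores are compared across cell-type labels with a tie-corrected
Kruskal–Wallis test plus pairwise two-sided rank-sum post-hocs under BH
adjustment. Cells from one tumor are not independent; an optional
per-tumor median aggregation (`aggregate_per_tumor`) is provided for
pseudo-replication-aware testing but is not the default, matching the
cell-level convention of the source analyses. Integration, clustering,
UMAP and marker finding are out of scope — the module scores
user-supplied labels.

## Cohort copy-number and survival statistics

GISTIC broad scores (samples × arms) are thresholded at ±`cutoff`
(default 0.3): the boundary value itself is called altered, a documented
inclusive choice (the cutoff definition does not state strictness, and
excluding the boundary would silently drop scores that round to exactly
0.3). Alteration frequencies are per-arm fractions within a subgroup;
burden is the per-sample count of arm gains/losses plus focal amp/del
counts consumed from GISTIC focal event tables (segmentation is never
recomputed here). The 6q-loss burden association excludes the marker arm
from the burden count and compares strata with a two-sided rank-sum test,
with the opposite call type tested identically as a negative control.
Survival uses Kaplan–Meier product-limit curves and the log-rank
(Mantel–Cox) χ² with 1 df (via lifelines). Group dichotomies come from a
generic helper supporting arm-call splits, top-quartile splits (≥ 75th
percentile, which yields 19 of 76 samples — the ceiling convention), and
mean splits.

## Synthetic study generator

The generator emulates the statistical structure of the real cohorts so
every stage runs end-to-end without downloads. Defaults are the study's
design conditions:

| quantity | default | rationale |
|---|---|---|
| ChIP cohorts | 9 PFA-like, 6 DMG-like samples | the consensus workflow's cohort sizes |
| genes | 200 on 2 chromosomes, ≥3× promoter-window spacing | keeps bodies and promoters provably disjoint |
| planted retained genes | 50 shared + 25 per-class specific at prevalence 0.95 | shared/specific structure with high but imperfect penetrance |
| bulk groups | 49 + 29 samples | the PFA1/PFA2 subtype sizes |
| bimodal mixture | N(2, 0.5²) / N(7, 0.5²) | well-separated log2 modes with density crossing at 4.5 |
| single cell | 400 cells, 300 genes, NB (r = 2), log(4) signature effect in one type | over-dispersed counts typical of scRNA-seq |
| subgroups | H3.3 = 42, H3.1 = 11, EZHIP = 8, PFA = 40 | DMG subgroup sizes of the validation cohort, with a PFA arm of similar scale |
| 1q-gain probabilities | 0.29 / 0.57 / 0.50 / 0.25 by subgroup | the reported ordering: highest in H3.1 |
| arm scores | baseline N(0, 0.05²), altered magnitude 0.4–0.8 | baseline essentially never crosses ±0.3 (P ≈ 2×10⁻⁹) |
| survival | exponential, median 24 months, hazard ratio 3 for 1q gain, uniform censoring on (0, 60) | a strong prognostic split at pediatric-glioma time scales |

Prevalence realization has two modes. The default `exact` mode plants a
gene's peak in exactly `floor(prevalence·n)` samples chosen at random, so
planted truth is well-defined per seed: prevalence strictly above the
consensus fraction is always recalled and strictly below always rejected.
The `bernoulli` mode flips an independent coin per sample, giving
Binomial(n, p) support — the right model for distributional tests, but
one under which "the planted set" is only realized in expectation (at
p = 0.95 a 6-sample cohort misses its 5/6 threshold ~3% of the time per
gene). Background peaks are confined to intergenic space, so they can
never create false gene support. Enhancer loci are drawn from distinct
intergenic gaps; planted super-enhancer loci get constituent peaks whose
signals are boosted 30× over the log-normal background so they dominate
the rank curve.

Each generator draws from a single `numpy` Generator seeded from
`(seed, crc32(stage_name))`: stages are statistically decoupled and the
same configuration reproduces byte-identical outputs. Every generator
returns a machine-readable truth sidecar; recovery tests consume only the
sidecar.

What the generator does **not** emulate: read-level data, realistic peak
shapes or genomic sequence, correlated gene–gene expression structure
beyond the planted effects, batch effects, microarray normalization
artifacts, doublets/ambient RNA in single-cell counts, or competing
risks in survival. Passing recovery tests therefore demonstrates the
correctness of the calling and testing machinery under the stated
statistical model, not robustness to the messier failure modes of real
cohorts.

## Numerical choices and degenerate inputs

* Consensus threshold uses strict `> fraction·n` (integer arithmetic via
  `floor + 1`), matching both worked examples (7/9, 5/6).
* SE tangent cutoff: slope strictly greater than 1; all-equal signals are
  a degenerate curve — zero super enhancers plus a warning.
* GSEA: if all hit scores are exactly 0 under weight > 0, hit increments
  fall back to equal weights; an empty same-sign permutation set leaves
  NES undefined (NaN) with a warning.
* KDE mode detection counts strict interior maxima plus monotone
  endpoints; fewer than two maxima → no threshold (`None`).
* `split_by_mean` labels values strictly above the mean as high, so an
  all-equal vector is all-low.
* Kruskal–Wallis on an all-identical pooled sample returns H = 0, p = 1
  rather than an error.
* Pipeline summaries round floats to 10 decimal places and sort JSON keys
  so reruns are byte-identical; the output directory path is excluded
  from the echoed parameters for the same reason.

## Problem sizes

The bundled demo study (200 genes, 15 ChIP samples, 78 + 91 bulk arrays,
400 cells, 101 copy-number samples) runs the full pipeline in well under a
minute; null calibrations use 2,000 replicates for the Kruskal–Wallis and
log-rank rates and 200 simulations × 99 permutations for GSEA p-value
uniformity. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerance bands while keeping the whole suite quick to
run.

## Known limitations

* The reciprocal-sharing step consumes candidate enhancer lists and SE
  calls; it does not reconstruct the upstream curation of published
  enhancer-associated gene lists.
* The GSEA engine supports the preranked mode only (no phenotype
  permutation), and pathway databases are out of scope — callers supply
  gene sets.
* Arm-call vocabularies assume the canonical 39 autosomal arms; sex
  chromosomes are accepted as extra columns but carry no special
  handling.
* Survival machinery covers two-group log-rank comparisons; no Cox
  models, no competing risks.
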