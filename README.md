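# k27shared

Comparative epigenomics of H3K27-altered diffuse midline gliomas (DMGs)
and posterior fossa group A (PFA) ependymomas.

Both tumor types suppress PRC2 — DMGs through the H3K27M oncohistone, most
PFAs through EZHIP overexpression — and globally lose the repressive
H3K27me3 mark. What they *keep* is informative: a consensus set of genes
that retain H3K27me3, shared H3K27ac super enhancers, heterogeneously
expressed retained genes that track tumor anatomic origin (HOX-like
bimodality), signature activity concentrated in specific single-cell
states, and recurrent arm-level copy-number events (1q gain, 6q loss) with
prognostic weight. `k27shared` is a tested, reusable implementation of
that comparative workflow for computational biologists who have per-sample
peak files, expression matrices, labeled single-cell counts, GISTIC arm
scores and survival tables — plus a synthetic-study generator with the
same statistical structure, so the entire pipeline runs and is tested
end-to-end without any external downloads.

## What it computes

* **Consensus H3K27me3-retained genes** (`k27shared.retained`): a sample
  supports a gene when ≥ 1 peak overlaps the gene body or its 2-kb
  upstream promoter; a gene is retained when supported by strictly more
  than two-thirds of a cohort — the threshold is `⌊f·n⌋ + 1`, i.e. 7/9
  and 5/6 at the default f = 2/3. Retained sets are partitioned into
  shared and subtype-specific genes.
* **Super enhancers and reciprocal sharing** (`k27shared.enhancers`):
  ROSE-style transitive stitching of H3K27ac peaks (12.5-kb gap), rank
  ordering by total signal, and a discrete tangent cutoff — with rank and
  signal scaled to unit axes, the cutoff is the first point where the
  curve's slope exceeds 1. A cohort-specific enhancer is promoted to
  shared if it overlaps a called super enhancer in ≥ 1 sample of the
  other cohort.
* **Bulk-expression statistics** (`k27shared.expression`): pooled-variance
  Student's t with Benjamini–Hochberg FDR, the ranking metric
  `(−log₁₀ q) × Δ`, a deterministic GSEA-preranked engine (weighted
  running sum, gene-label permutations, meandiv NES), probe collapsing by
  maximal reference-cohort mean, per-gene SD heterogeneity, KDE-based
  bimodal splitting at the local minimum between modes, mean splits with
  co-expression differences, and OLS fits with R².
* **Single-cell signature scoring** (`k27shared.singlecell`): per-cell
  mean module scores and AUCell-style recovery AUCs over the top 5% of
  each cell's expression ranking, compared across cell types by
  Kruskal–Wallis with BH-adjusted rank-sum post-hocs.
* **Cohort statistics** (`k27shared.cohort`): GISTIC broad-score
  thresholding at ±0.3, per-subgroup alteration frequencies, per-sample
  burden, marker-arm burden associations (rank-sum, marker excluded), and
  Kaplan–Meier curves with the log-rank (Mantel–Cox) test.
* **Synthetic studies** (`k27shared.simulate`) and an orchestrating
  pipeline + CLI (`k27shared.pipeline`, `k27shared` console script).

See `docs/methods.md` for the statistical details, defaults and
limitations.

## Worked example

Run the full pipeline on the bundled synthetic study (9 PFA-like + 6
DMG-like ChIP samples over 200 genes with 50 planted shared retained
genes, PFA1/PFA2-like bulk arrays, 400 single cells with an OPC-like
signature effect, and an NCI-like copy-number/survival cohort):

```python
from k27shared.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1, out_dir="demo_run"))

r = summary["retained"]
print(f"consensus thresholds : {r['thresholds']}")
print(f"retained per cohort  : {r['n_retained']}")
print(f"shared retained genes: {r['n_shared']} "
      f"(discordant vs planted truth: {r['n_discordant_vs_planted']})")
g = summary["expression"]["gsea"]
print(f"GSEA planted set     : ES={g['es']:.3f} NES={g['nes']:.2f} p={g['p_perm']:.4f}")
print(f"bimodal threshold    : {summary['expression']['bimodal_threshold']:.2f}")
s = summary["scscore"]
print(f"top cell type (mean) : {s['mean']['top_type_by_median']} "
      f"(H={s['mean']['kruskal_h']:.1f}, p={s['mean']['kruskal_p']:.1e})")
k = summary["cohort"]["logrank"]
print(f"1q-gain log-rank     : chi2={k['chi2']:.2f}, p={k['p']:.2e}")
```

prints

```text
consensus thresholds : {'DMG': 5, 'PFA': 7}
retained per cohort  : {'DMG': 75, 'PFA': 75}
shared retained genes: 50 (discordant vs planted truth: 0)
GSEA planted set     : ES=0.994 NES=1.16 p=0.0050
bimodal threshold    : 4.48
top cell type (mean) : OPC-like (H=247.8, p=1.9e-53)
1q-gain log-rank     : chi2=12.40, p=4.29e-04
```

Reading this: each cohort's retained call needs 7 of 9 (PFA) or 5 of 6
(DMG) supporting samples; each recovers its 75 planted genes (50 shared +
25 class-specific) and the shared intersection equals the planted 50
exactly. The planted differential-expression gene set is strongly
enriched in the ranked list (ES near 1). The bimodal HOXA2-like gene
splits at 4.48, close to the true mixture density crossing of 4.5 for the
N(2, 0.5²)/N(7, 0.5²) components. The planted signature-enriched OPC-like
cell population scores highest, and the planted hazard ratio of 3 for
1q-gain samples yields a clearly significant log-rank split. Per-stage
tables land under `demo_run/`, with a byte-stable `summary.json` and a
`run.log` echoing every threshold applied.

The same run is available from the shell:

```bash
k27shared run-all --seed 1 --out demo_run
```

and the individual stages (`simulate`, `retained`, `enhancers`,
`expression`, `scscore`, `cohort`) accept manifests and plain TSV/BED
inputs for use on real data — see `k27shared <stage> --help`.

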