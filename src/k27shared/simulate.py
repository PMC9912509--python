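"""Synthetic study generator emulating the comparative-analysis inputs.

Every analysis stage in this package was designed against external tumor
cohorts (ChIP-seq peak BEDs, bulk microarray matrices, single-cell counts,
GISTIC arm scores, survival tables).  This module generates inputs with
the same statistical structure — per-gene peak prevalence across samples,
rank-dominant enhancer signals, bimodal log-expression, cell-type-enriched
signatures, subgroup-specific arm alterations, and group-specific hazards
— together with machine-readable truth sidecars, so every stage is
testable end-to-end without downloads.

Determinism: each generator draws from a single ``numpy`` Generator seeded
from ``(config.seed, crc32(stage_name))``, so stages are decoupled and the
same config yields byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome import GeneModel, GenomicInterval, make_gene_regions
from .retained import PeakCohort
from .singlecell import CellExpression

__all__ = [
    "SimConfig",
    "stage_rng",
    "gen_genome",
    "gen_peak_cohort",
    "gen_enhancer_cohort",
    "gen_bulk_expression",
    "gen_sc_cohort",
    "gen_cohort_tables",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic comparative study.

    Defaults mirror the study conditions the analyses were built for:
    9 PFA-like and 6 DMG-like ChIP-seq samples with 200 annotated genes,
    50 shared retained genes planted at prevalence 0.95 plus 25 per-class
    specific genes; PFA1/PFA2-like bulk groups of 49 and 29 samples with
    bimodal genes mixing N(2, 0.5^2) and N(7, 0.5^2); negative-binomial
    single-cell counts with a log(4) signature effect in one cell type;
    NCI-cohort-like subgroup sizes (H3.3 = 42, H3.1 = 11, EZHIP = 8,
    PFA = 40) with subgroup-specific 1q-gain/6q-loss probabilities and a
    1q-gain hazard ratio of 3 on exponential survival times.
    """

    seed: int = 0

    # genome
    n_genes: int = 200
    n_chroms: int = 2
    promoter_bp: int = 2000
    gene_length_range: tuple[int, int] = (5_000, 15_000)
    chrom_length: int | None = None

    # peak cohorts (ChIP-seq consensus stage)
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"PFA": 9, "DMG": 6}
    )
    n_shared_retained: int = 50
    n_specific_retained: int = 25  # per class
    planted_prevalence: float = 0.95
    prevalence_mode: str = "exact"  # "exact" or "bernoulli"
    background_peaks_per_sample: int = 30
    peak_width_range: tuple[int, int] = (500, 2_000)

    # enhancer landscape
    enhancers_per_sample: int = 30
    n_shared_enhancer_loci: int = 5
    n_specific_enhancer_loci: int = 5  # per class
    enhancer_signal_lognorm: tuple[float, float] = (1.0, 0.5)  # mu, sigma of log
    dominant_signal_factor: float = 30.0

    # bulk expression
    bulk_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"PFA1": 49, "PFA2": 29}
    )
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    bimodal_means: tuple[float, float] = (2.0, 7.0)
    bimodal_sd: float = 0.5
    bimodal_high_prob: dict[str, float] = field(
        default_factory=lambda: {"PFA1": 0.9, "PFA2": 0.1}
    )
    n_multiprobe_genes: int = 10
    effect_size: float = 2.0

    # single-cell
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "OPC-like": 0.3,
            "AC-like": 0.3,
            "OC-like": 0.2,
            "NPC-like": 0.2,
        }
    )
    n_cells: int = 400
    n_sc_genes: int = 300
    n_tumors: int = 4
    nb_dispersion: float = 2.0
    sc_baseline_log_mean: float = 0.0
    sc_baseline_log_sd: float = 1.0
    signature_effect: float = float(np.log(4.0))
    n_signature_genes: int = 20

    # cohort tables
    subgroup_sizes: dict[str, int] = field(
        default_factory=lambda: {"H3.3": 42, "H3.1": 11, "EZHIP": 8, "PFA": 40}
    )
    arm_alteration_probs: dict[str, dict[str, tuple[str, float]]] = field(
        default_factory=lambda: {
            "H3.3": {"1q": ("gain", 0.29), "6q": ("loss", 0.15)},
            "H3.1": {"1q": ("gain", 0.57), "6q": ("loss", 0.15)},
            "EZHIP": {"1q": ("gain", 0.50), "6q": ("loss", 0.15)},
            "PFA": {"1q": ("gain", 0.25), "6q": ("loss", 0.15)},
        }
    )
    baseline_arm_sd: float = 0.05
    altered_score_range: tuple[float, float] = (0.4, 0.8)
    focal_rates: dict[str, float] = field(
        default_factory=lambda: {"H3.3": 5.0, "H3.1": 1.0, "EZHIP": 1.0, "PFA": 0.5}
    )
    median_survival_months: float = 24.0
    hazard_ratio: float = 3.0
    censoring_max_months: float = 60.0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_prevalence <= 1:
            raise ValueError("planted_prevalence must lie in [0, 1]")
        if self.prevalence_mode not in ("exact", "bernoulli"):
            raise ValueError("prevalence_mode must be 'exact' or 'bernoulli'")
        if self.bimodal_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if abs(self.bimodal_means[1] - self.bimodal_means[0]) < 2 * self.bimodal_sd:
            raise ValueError("bimodal component means must be >= 2 sd apart")


def stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    """Generator seeded from (config.seed, crc32(stage)) — stage-decoupled."""
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# genome


def gen_genome(config: SimConfig) -> list[GeneModel]:
    """Lay out non-overlapping genes with >= 3x promoter-window spacing.

    Strands alternate, so consecutive promoters can face each other; the
    3x spacing keeps gene bodies and both promoters disjoint.  Gene ids
    are zero-padded (`G0001` ...) so lexicographic order equals genomic
    order.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = stage_rng(config, "genome")
    spacing = 3 * config.promoter_bp
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    genes: list[GeneModel] = []
    width = len(str(config.n_genes))
    gi = 0
    for c in range(1, config.n_chroms + 1):
        pos = spacing
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length_range))
            start, end = pos, pos + length
            if config.chrom_length is not None and end + spacing > config.chrom_length:
                raise ValueError(
                    f"chromosome chr{c} too small for requested gene layout"
                )
            genes.append(
                GeneModel(
                    gene_id=f"G{gi + 1:0{width}d}",
                    chrom=f"chr{c}",
                    strand="+" if gi % 2 == 0 else "-",
                    tx_start=start,
                    tx_end=end,
                )
            )
            pos = end + spacing + int(rng.integers(0, config.promoter_bp))
            gi += 1
    return genes


# ---------------------------------------------------------------------------
# ChIP-seq peak cohorts


def _plant_peak(
    rng: np.random.Generator, span: tuple[str, int, int], width_range: tuple[int, int]
) -> GenomicInterval:
    chrom, lo, hi = span
    width = int(rng.integers(*width_range))
    width = min(width, hi - lo)
    start = int(rng.integers(lo, hi - width + 1))
    return GenomicInterval(chrom, start, start + width)


def gen_peak_cohort(
    config: SimConfig,
    genome: list[GeneModel],
    truth: dict[str, float],
    tumor_class: str,
) -> tuple[PeakCohort, pd.DataFrame]:
    """Per-sample peak sets with planted per-gene prevalences.

    ``truth`` maps gene ids to the fraction of samples whose peaks should
    cover the gene (body or promoter).  In the default ``exact`` mode a
    gene's peak is planted in exactly ``floor(prevalence x n)`` samples,
    chosen at random, so any prevalence strictly above the consensus
    fraction is recalled and any strictly below is rejected, for every
    seed.  In ``bernoulli`` mode each sample flips an independent coin.
    Background peaks land in intergenic space only.  The returned truth
    table records the planted prevalence and realized support per gene.
    """
    if any(not 0 <= p <= 1 for p in truth.values()):
        raise ValueError("prevalences must lie in [0, 1]")
    n = config.cohort_sizes[tumor_class]
    rng = stage_rng(config, f"peaks:{tumor_class}")
    regions = make_gene_regions(genome, config.promoter_bp)
    span_by_gene = {}
    for r in regions:
        lo = min(r.body.start, r.promoter.start)
        hi = max(r.body.end, r.promoter.end)
        span_by_gene[r.gene_id] = (r.body.chrom, lo, hi)

    sample_ids = [f"{tumor_class}_{i + 1:02d}" for i in range(n)]
    peaks: dict[str, list[GenomicInterval]] = {s: [] for s in sample_ids}
    support: dict[str, int] = {}
    for gene_id in sorted(truth):
        prevalence = truth[gene_id]
        if config.prevalence_mode == "exact":
            k = int(np.floor(prevalence * n))
            chosen = rng.choice(n, size=k, replace=False)
        else:
            chosen = np.flatnonzero(rng.random(n) < prevalence)
        support[gene_id] = len(chosen)
        for si in chosen:
            peaks[sample_ids[si]].append(
                _plant_peak(rng, span_by_gene[gene_id], config.peak_width_range)
            )

    # background peaks: intergenic space between consecutive gene spans
    gaps = _intergenic_gaps(genome, config.promoter_bp)
    for s in sample_ids:
        for _ in range(config.background_peaks_per_sample):
            gap = gaps[rng.integers(len(gaps))]
            peaks[s].append(_plant_peak(rng, gap, config.peak_width_range))

    truth_table = pd.DataFrame(
        {
            "prevalence": pd.Series(truth),
            "support": pd.Series(support),
            "n_samples": n,
        }
    ).rename_axis("gene_id")
    return PeakCohort(tumor_class=tumor_class, samples=peaks), truth_table


def _intergenic_gaps(
    genome: list[GeneModel], promoter_bp: int, min_width: int = 2_500
) -> list[tuple[str, int, int]]:
    """Intervals guaranteed clear of every gene body and promoter."""
    margin = promoter_bp + 100
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome:
        by_chrom.setdefault(g.chrom, []).append(g)
    gaps = []
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.tx_start)
        for a, b in zip(genes, genes[1:]):
            lo, hi = a.tx_end + margin, b.tx_start - margin
            if hi - lo >= min_width:
                gaps.append((chrom, lo, hi))
    if not gaps:
        raise ValueError("genome layout leaves no intergenic space for background")
    return gaps


# ---------------------------------------------------------------------------
# enhancer landscape


def gen_enhancer_cohort(
    config: SimConfig, genome: list[GeneModel]
) -> tuple[dict[str, dict[str, list[GenomicInterval]]], pd.DataFrame]:
    """Per-sample H3K27ac peak sets with planted shared/specific SE loci.

    A set of intergenic enhancer loci is split into shared, A-specific and
    B-specific groups.  Active loci in a sample receive 2–3 constituent
    peaks (within stitching range of each other) with log-normal signals;
    planted super-enhancer loci are boosted by ``dominant_signal_factor``
    so they dominate the rank curve.  Remaining background loci give the
    curve its body.  Returns ``{tumor_class: {sample: peaks}}`` plus a
    locus truth table (chrom, start, end, class).
    """
    rng = stage_rng(config, "enhancers")
    gaps = _intergenic_gaps(genome, config.promoter_bp)
    classes = list(config.cohort_sizes)
    if len(classes) != 2:
        raise ValueError("enhancer generator expects exactly 2 tumor classes")
    n_planted = config.n_shared_enhancer_loci + 2 * config.n_specific_enhancer_loci
    n_background = max(config.enhancers_per_sample - n_planted, 10)
    n_loci = n_planted + n_background
    if n_loci > len(gaps):
        raise ValueError(
            f"genome has {len(gaps)} intergenic gaps but {n_loci} enhancer "
            "loci requested"
        )
    loci = []
    for gi in rng.choice(len(gaps), size=n_loci, replace=False):
        chrom, lo, hi = gaps[gi]
        width = 3_000
        start = int(rng.integers(lo, max(lo + 1, hi - width)))
        loci.append((chrom, start, start + width))
    kinds = (
        ["shared"] * config.n_shared_enhancer_loci
        + [f"{classes[0]}_specific"] * config.n_specific_enhancer_loci
        + [f"{classes[1]}_specific"] * config.n_specific_enhancer_loci
        + ["background"] * n_background
    )
    mu, sigma = config.enhancer_signal_lognorm
    cohorts: dict[str, dict[str, list[GenomicInterval]]] = {}
    for cls in classes:
        cohorts[cls] = {}
        for i in range(config.cohort_sizes[cls]):
            sample = f"{cls}_{i + 1:02d}"
            peaks: list[GenomicInterval] = []
            for (chrom, lo, hi), kind in zip(loci, kinds):
                active = kind in ("shared", f"{cls}_specific", "background")
                if not active:
                    continue
                boost = (
                    config.dominant_signal_factor
                    if kind != "background"
                    else 1.0
                )
                n_constituents = int(rng.integers(2, 4))
                step = (hi - lo) // n_constituents
                for c in range(n_constituents):
                    p_lo = lo + c * step
                    width = int(rng.integers(400, max(401, step // 2)))
                    signal = float(rng.lognormal(mu, sigma)) * boost
                    peaks.append(
                        GenomicInterval(
                            chrom, p_lo, min(p_lo + width, hi), score=signal
                        )
                    )
            cohorts[cls][sample] = peaks
    truth = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "kind": k}
            for (c, s, e), k in zip(loci, kinds)
        ]
    )
    return cohorts, truth


# ---------------------------------------------------------------------------
# bulk expression


def gen_bulk_expression(
    config: SimConfig,
    gene_ids: list[str],
    bimodal_genes: list[str] | None = None,
    group_effects: dict[str, dict[str, float]] | None = None,
    group_sizes: dict[str, int] | None = None,
    stage: str = "bulk",
) -> tuple[ExpressionMatrix, dict]:
    """Log2 expression with planted bimodal genes and group effects.

    Baseline values are N(baseline_mean, baseline_sd^2).  Bimodal genes
    draw from a two-component normal mixture whose high component is
    chosen per sample with the sample group's ``bimodal_high_prob``
    (component labels are recorded in the truth).  ``group_effects`` maps
    gene -> {group: shift} and is added on top.  The first
    ``n_multiprobe_genes`` genes get a second, dimmer probe so
    probe-collapsing has work to do.
    """
    rng = stage_rng(config, stage)
    bimodal_genes = list(bimodal_genes or [])
    group_effects = group_effects or {}
    group_sizes = group_sizes or config.bulk_group_sizes
    samples, groups = [], {}
    for grp, size in group_sizes.items():
        for i in range(size):
            sid = f"{grp}_{i + 1:03d}"
            samples.append(sid)
            groups[sid] = grp
    lo_mean, hi_mean = config.bimodal_means
    values = {}
    components: dict[str, dict[str, int]] = {}
    for gene in gene_ids:
        if gene in bimodal_genes:
            high = np.array(
                [
                    rng.random() < config.bimodal_high_prob.get(groups[s], 0.5)
                    for s in samples
                ]
            )
            mean = np.where(high, hi_mean, lo_mean)
            row = rng.normal(mean, config.bimodal_sd)
            components[gene] = {
                s: int(h) for s, h in zip(samples, high)
            }
        else:
            row = rng.normal(config.baseline_mean, config.baseline_sd, len(samples))
        for grp_gene, shifts in group_effects.items():
            if grp_gene == gene:
                shift = np.array([shifts.get(groups[s], 0.0) for s in samples])
                row = row + shift
        values[gene] = row
    probe_rows, probe_map = {}, {}
    for gi, gene in enumerate(gene_ids):
        probe = f"{gene}_p1"
        probe_rows[probe] = values[gene]
        probe_map[probe] = gene
        if gi < config.n_multiprobe_genes:
            probe2 = f"{gene}_p0"  # lexicographically before _p1; dimmer
            probe_rows[probe2] = values[gene] - 2.0 + rng.normal(0, 0.1, len(samples))
            probe_map[probe2] = gene
    matrix = ExpressionMatrix(
        values=pd.DataFrame(probe_rows, index=samples).T,
        probe_map=probe_map,
        sample_groups=groups,
    )
    truth = {
        "bimodal_genes": bimodal_genes,
        "components": components,
        "group_effects": group_effects,
        "mixture_means": config.bimodal_means,
        "mixture_sd": config.bimodal_sd,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# single cell


def gen_sc_cohort(
    config: SimConfig,
    signature_genes: list[str] | None = None,
    enriched_cell_type: str = "OPC-like",
) -> tuple[CellExpression, dict]:
    """Negative-binomial counts with a signature boosted in one cell type.

    Per-gene baseline means are log-normal; counts are NB with fixed
    dispersion (``r = nb_dispersion``, ``p = r / (r + mu)``).  Signature
    genes' means are multiplied by ``exp(signature_effect)`` in the
    enriched cell type.  Cells get tumor-of-origin labels drawn uniformly
    over ``n_tumors`` tumors per cell type.
    """
    if enriched_cell_type not in config.cell_type_proportions:
        raise ValueError(
            f"enriched type {enriched_cell_type!r} not among configured types"
        )
    rng = stage_rng(config, "singlecell")
    width = len(str(config.n_sc_genes))
    genes = [f"SG{i + 1:0{width}d}" for i in range(config.n_sc_genes)]
    if signature_genes is None:
        signature_genes = genes[: config.n_signature_genes]
    unknown = set(signature_genes) - set(genes)
    if unknown:
        raise ValueError(f"signature genes not in simulated universe: {unknown}")
    types = list(config.cell_type_proportions)
    probs = np.array([config.cell_type_proportions[t] for t in types])
    probs = probs / probs.sum()
    counts_per_type = rng.multinomial(config.n_cells, probs)
    base_mu = rng.lognormal(
        config.sc_baseline_log_mean, config.sc_baseline_log_sd, config.n_sc_genes
    )
    sig_mask = np.isin(genes, signature_genes)
    r = config.nb_dispersion
    cols, cell_types, tumors = {}, {}, {}
    ci = 0
    for t, n_t in zip(types, counts_per_type):
        mu = base_mu.copy()
        if t == enriched_cell_type:
            mu[sig_mask] *= float(np.exp(config.signature_effect))
        for _ in range(n_t):
            cell = f"cell_{ci + 1:04d}"
            cols[cell] = rng.negative_binomial(r, r / (r + mu))
            cell_types[cell] = t
            tumors[cell] = f"tumor_{rng.integers(config.n_tumors) + 1}"
            ci += 1
    values = pd.DataFrame(cols, index=genes)
    cells = CellExpression(
        values=values,
        cell_type=pd.Series(cell_types),
        tumor=pd.Series(tumors),
        is_raw_counts=True,
    )
    truth = {
        "signature_genes": list(signature_genes),
        "enriched_cell_type": enriched_cell_type,
        "effect": config.signature_effect,
    }
    return cells, truth


# ---------------------------------------------------------------------------
# cohort tables


def gen_cohort_tables(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame, dict]:
    """Arm scores, subgroup labels, focal events, and survival times.

    Baseline arm scores are N(0, baseline_arm_sd^2) — essentially never
    past the +/-0.3 call cutoff.  Per subgroup, designated arms are
    altered with the configured probability at a score magnitude drawn
    from ``altered_score_range``.  Focal amp/del counts are Poisson with
    subgroup-specific rates.  Survival times are exponential with the
    baseline hazard implied by ``median_survival_months``, multiplied by
    ``hazard_ratio`` for 1q-gain samples; censoring is uniform on
    (0, censoring_max_months).
    """
    from .cohort import AUTOSOMAL_ARMS

    rng = stage_rng(config, "cohort")
    samples, subgroup = [], {}
    for grp, size in config.subgroup_sizes.items():
        for i in range(size):
            sid = f"{grp}_{i + 1:03d}"
            samples.append(sid)
            subgroup[sid] = grp
    scores = pd.DataFrame(
        rng.normal(0, config.baseline_arm_sd, (len(samples), len(AUTOSOMAL_ARMS))),
        index=samples,
        columns=list(AUTOSOMAL_ARMS),
    )
    lo, hi = config.altered_score_range
    planted: dict[str, dict[str, str]] = {s: {} for s in samples}
    for s in samples:
        for arm, (direction, prob) in config.arm_alteration_probs[subgroup[s]].items():
            if rng.random() < prob:
                mag = rng.uniform(lo, hi)
                scores.loc[s, arm] = mag if direction == "gain" else -mag
                planted[s][arm] = direction
    focal_rows = []
    for s in samples:
        lam = config.focal_rates[subgroup[s]]
        for kind in ("amp", "del"):
            for k in range(rng.poisson(lam)):
                focal_rows.append(
                    {"sample": s, "type": kind, "locus": f"locus_{k + 1}"}
                )
    focal = pd.DataFrame(focal_rows, columns=["sample", "type", "locus"])
    gain_1q = pd.Series({s: "1q" in planted[s] for s in samples})
    base_hazard = np.log(2) / config.median_survival_months
    hazard = base_hazard * np.where(gain_1q[samples], config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0, config.censoring_max_months, len(samples))
    surv = pd.DataFrame(
        {
            "sample": samples,
            "time": np.minimum(event_time, censor_time),
            "event": (event_time <= censor_time).astype(int),
            "group": gain_1q[samples].to_numpy(),
        }
    ).set_index("sample")
    truth = {
        "planted_alterations": planted,
        "hazard_ratio": config.hazard_ratio,
        "base_hazard": float(base_hazard),
    }
    return scores, pd.Series(subgroup), focal, surv, truth
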