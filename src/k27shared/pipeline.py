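"""End-to-end orchestration of the comparative analysis.

``run_pipeline`` wires the stages together in the order the analyses
build on each other — simulate inputs, call the consensus
H3K27me3-retained signature, call and reconcile super enhancers, run the
bulk-expression statistics, score the signature in single cells, and
compute the cohort copy-number/survival statistics — writing per-stage
TSV outputs, a run log echoing every threshold applied, and a
deterministic ``summary.json`` (sorted keys, no timestamps, input content
hashes), so reruns of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import enhancers as enh_mod
from . import expression as expr_mod
from . import retained as ret_mod
from . import simulate as sim_mod
from . import singlecell as sc_mod
from .genome import read_bed, write_bed, write_gene_table

logger = logging.getLogger("k27shared")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    Defaults equal the published analysis parameters: 2-kb promoters,
    strict two-thirds consensus, 12.5-kb enhancer stitching, +/-0.3 arm
    cutoff, 15–500 GSEA set-size gates, top-5% AUC window, top-quartile
    expression split.
    """

    seed: int = 0
    out_dir: str = "k27shared_run"
    promoter_bp: int = 2000
    fraction: float = 2.0 / 3.0
    gap_bp: int = 12_500
    arm_cutoff: float = 0.3
    top_fraction: float = 0.05
    n_perm: int = 200
    min_size: int = 15
    max_size: int = 500
    n_effect_genes: int = 30
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = sim_mod.SimConfig(**sim_raw)
            cfg.sim.seed = cfg.seed
            cfg.sim.promoter_bp = cfg.promoter_bp
        return cfg

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.sim.promoter_bp = self.promoter_bp


def validate_config(config: RunConfig) -> list[str]:
    """Collect every validation error (empty list means the config is ok)."""
    errors: list[str] = []
    if not 0 < config.fraction < 1:
        errors.append(f"fraction out of range (0, 1): {config.fraction}")
    if config.promoter_bp <= 0:
        errors.append(f"promoter_bp must be positive: {config.promoter_bp}")
    if config.gap_bp < 0:
        errors.append(f"gap_bp must be >= 0: {config.gap_bp}")
    if config.arm_cutoff <= 0:
        errors.append(f"arm_cutoff must be positive: {config.arm_cutoff}")
    if not 0 < config.top_fraction < 1:
        errors.append(f"top_fraction out of range (0, 1): {config.top_fraction}")
    if config.n_perm < 1:
        errors.append(f"n_perm must be >= 1: {config.n_perm}")
    if not 0 < config.min_size <= config.max_size:
        errors.append(
            f"set-size gates invalid: [{config.min_size}, {config.max_size}]"
        )
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, sig: int = 10):
    """Round floats to significant digits so summaries are bit-stable.

    Significant (not decimal) digits, so tiny p-values survive rounding.
    """
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated study and write the report bundle.

    Returns the summary dictionary that is also written to
    ``<out_dir>/summary.json``.  A stage failure raises with the stage
    name; outputs of completed stages are retained on disk.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"parameters": _round_floats(_echo_params(config))}
    try:
        stage = "simulate"
        inputs = _stage_simulate(config, out / "inputs")
        summary["input_hashes"] = {
            name: _sha256(path) for name, path in sorted(inputs["files"].items())
        }
        stage = "retained"
        summary["retained"] = _stage_retained(config, inputs, out / "retained")
        stage = "enhancers"
        summary["enhancers"] = _stage_enhancers(config, inputs, out / "enhancers")
        stage = "expression"
        summary["expression"] = _stage_expression(config, inputs, out / "expression")
        stage = "scscore"
        summary["scscore"] = _stage_scscore(config, inputs, out / "scscore")
        stage = "cohort"
        summary["cohort"] = _stage_cohort(config, inputs, out / "cohort")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _echo_params(config: RunConfig) -> dict:
    # out_dir is a filesystem detail, not an analysis parameter: leaving it
    # out keeps summary.json identical across runs in different locations
    params = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k not in ("sim", "out_dir")
    }
    logger.info("parameters: %s", params)
    return params


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, indir: Path) -> dict:
    indir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    genome = sim_mod.gen_genome(sim)
    files: dict[str, Path] = {}
    genes_path = indir / "genes.tsv"
    write_gene_table(genome, genes_path)
    files["genes"] = genes_path

    # planted retained-gene truth: shared + per-class specific prevalences
    gene_ids = [g.gene_id for g in genome]
    n_sh, n_sp = sim.n_shared_retained, sim.n_specific_retained
    classes = list(sim.cohort_sizes)
    shared = gene_ids[:n_sh]
    specific = {
        classes[0]: gene_ids[n_sh : n_sh + n_sp],
        classes[1]: gene_ids[n_sh + n_sp : n_sh + 2 * n_sp],
    }
    cohorts, peak_truths = {}, {}
    for cls in classes:
        truth = {g: sim.planted_prevalence for g in shared + specific[cls]}
        cohort, truth_table = sim_mod.gen_peak_cohort(sim, genome, truth, cls)
        cohorts[cls] = cohort
        peak_truths[cls] = truth_table
        truth_table.to_csv(indir / f"peak_truth_{cls}.tsv", sep="\t")
        for sample, peaks in cohort.samples.items():
            p = indir / f"peaks_{sample}.bed"
            write_bed(peaks, p)
            files[f"peaks_{sample}"] = p
        logger.info(
            "simulated %d %s samples (%d planted genes)",
            cohort.n_samples, cls, len(truth),
        )

    enh_cohorts, enh_truth = sim_mod.gen_enhancer_cohort(sim, genome)
    enh_truth.to_csv(indir / "enhancer_truth.tsv", sep="\t", index=False)
    for cls, samples in enh_cohorts.items():
        for sample, peaks in samples.items():
            p = indir / f"h3k27ac_{sample}.bed"
            write_bed(peaks, p)
            files[f"h3k27ac_{sample}"] = p

    effect_genes = gene_ids[-config.n_effect_genes :]
    bimodal_gene = gene_ids[n_sh]  # first class-specific gene doubles as HOXA2-like
    group_names = list(sim.bulk_group_sizes)
    effects = {g: {group_names[0]: sim.effect_size} for g in effect_genes}
    bulk_a, bulk_truth_a = sim_mod.gen_bulk_expression(
        sim, gene_ids, bimodal_genes=[bimodal_gene], group_effects=effects,
        stage="bulk:A",
    )
    bulk_b, _ = sim_mod.gen_bulk_expression(
        sim, gene_ids, bimodal_genes=[bimodal_gene],
        group_sizes={"pons": 65, "thalamus": 26}, stage="bulk:B",
    )
    expr_path = indir / "expression_A.tsv"
    bulk_a.values.to_csv(expr_path, sep="\t")
    files["expression_A"] = expr_path
    bulk_b.values.to_csv(indir / "expression_B.tsv", sep="\t")
    files["expression_B"] = indir / "expression_B.tsv"

    cells, sc_truth = sim_mod.gen_sc_cohort(sim)
    sc_path = indir / "sc_counts.tsv"
    cells.values.to_csv(sc_path, sep="\t")
    files["sc_counts"] = sc_path
    meta = pd.DataFrame({"cell_type": cells.cell_type, "tumor": cells.tumor})
    meta.to_csv(indir / "sc_metadata.tsv", sep="\t")
    files["sc_metadata"] = indir / "sc_metadata.tsv"

    scores, subgroup, focal, surv, cohort_truth = sim_mod.gen_cohort_tables(sim)
    scores.to_csv(indir / "arm_scores.tsv", sep="\t")
    files["arm_scores"] = indir / "arm_scores.tsv"
    focal.to_csv(indir / "focal_events.tsv", sep="\t", index=False)
    surv.to_csv(indir / "survival.tsv", sep="\t")
    files["survival"] = indir / "survival.tsv"

    return {
        "files": files,
        "genome": genome,
        "cohorts": cohorts,
        "peak_truths": peak_truths,
        "planted_shared": set(shared),
        "planted_specific": {k: set(v) for k, v in specific.items()},
        "enh_cohorts": enh_cohorts,
        "enh_truth": enh_truth,
        "bulk_a": bulk_a,
        "bulk_b": bulk_b,
        "bulk_truth": bulk_truth_a,
        "bimodal_gene": bimodal_gene,
        "effect_genes": effect_genes,
        "cells": cells,
        "sc_truth": sc_truth,
        "arm_scores": scores,
        "subgroup": subgroup,
        "focal": focal,
        "surv": surv,
        "cohort_truth": cohort_truth,
    }


def _stage_retained(config: RunConfig, inputs: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    from .genome import make_gene_regions

    regions = make_gene_regions(inputs["genome"], config.promoter_bp)
    retained_sets: dict[str, set[str]] = {}
    for cls, cohort in inputs["cohorts"].items():
        # round-trip through the BED files written by the simulate stage
        reread = ret_mod.PeakCohort(
            tumor_class=cls,
            samples={
                s: read_bed(inputs["files"][f"peaks_{s}"])
                for s in cohort.samples
            },
        )
        k = ret_mod.consensus_threshold(reread.n_samples, config.fraction)
        logger.info("consensus threshold for %s: %d/%d", cls, k, reread.n_samples)
        table = ret_mod.consensus_table(reread, regions, config.fraction)
        pd.DataFrame(
            [dataclasses.asdict(c) for c in table]
        ).to_csv(outdir / f"support_{cls}.tsv", sep="\t", index=False)
        retained_sets[cls] = {c.gene_id for c in table if c.retained}
        (outdir / f"retained_{cls}.txt").write_text(
            "\n".join(sorted(retained_sets[cls])) + "\n"
        )
    classes = sorted(retained_sets)
    shared, a_only, b_only = ret_mod.shared_and_specific(
        retained_sets[classes[0]], retained_sets[classes[1]]
    )
    for name, s in (
        ("shared", shared),
        (f"{classes[0]}_only", a_only),
        (f"{classes[1]}_only", b_only),
    ):
        (outdir / f"{name}.txt").write_text("\n".join(sorted(s)) + "\n")
    thresholds = {
        cls: ret_mod.consensus_threshold(
            inputs["cohorts"][cls].n_samples, config.fraction
        )
        for cls in classes
    }
    inputs["shared_retained"] = shared
    return {
        "thresholds": thresholds,
        "n_retained": {cls: len(retained_sets[cls]) for cls in classes},
        "n_shared": len(shared),
        "n_specific": {classes[0]: len(a_only), classes[1]: len(b_only)},
        "shared_equals_planted": shared == inputs["planted_shared"],
        "n_discordant_vs_planted": len(
            shared ^ inputs["planted_shared"]
        ),
    }


def _stage_enhancers(config: RunConfig, inputs: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    classes = list(inputs["enh_cohorts"])
    se_calls: dict[str, dict[str, enh_mod.SECallResult]] = {}
    n_super = {}
    for cls in classes:
        se_calls[cls] = {}
        for sample in inputs["enh_cohorts"][cls]:
            peaks = read_bed(inputs["files"][f"h3k27ac_{sample}"])
            stitched = enh_mod.stitch(peaks, config.gap_bp)
            call = enh_mod.call_super_enhancers(stitched)
            se_calls[cls][sample] = call
            rows = [
                {
                    "rank": i,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "signal": e.signal,
                    "is_super": i >= call.cutoff_index,
                }
                for i, e in enumerate(call.ranked)
            ]
            pd.DataFrame(rows).to_csv(
                outdir / f"se_{sample}.tsv", sep="\t", index=False
            )
        n_super[cls] = {s: len(c.super) for s, c in se_calls[cls].items()}
    truth = inputs["enh_truth"]
    result: dict = {"n_super": n_super}
    from .genome import GenomicInterval

    for cls, other in (classes, classes[::-1]):
        spec = truth[truth["kind"] == f"{cls}_specific"]
        candidates = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in spec.itertuples()
        ]
        promoted, still = enh_mod.reciprocal_share(candidates, se_calls[other])
        write_bed(promoted, outdir / f"{cls}_promoted_shared.bed")
        write_bed(still, outdir / f"{cls}_still_specific.bed")
        result[f"{cls}_promoted"] = len(promoted)
        result[f"{cls}_still_specific"] = len(still)
        logger.info(
            "%s-specific enhancers: %d promoted to shared, %d remain specific",
            cls, len(promoted), len(still),
        )
    return result


def _stage_expression(config: RunConfig, inputs: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    bulk_a, bulk_b = inputs["bulk_a"], inputs["bulk_b"]
    groups = sorted(set(bulk_a.sample_groups.values()))
    collapsed = expr_mod.collapse_probes(bulk_a, reference_group=groups[0])
    de = expr_mod.diff_expression(collapsed, groups[0], groups[1])
    de_df = pd.DataFrame([dataclasses.asdict(d) for d in de])
    de_df.to_csv(outdir / "de.tsv", sep="\t", index=False)
    ranked = {d.gene_id: d.rank_score for d in de}
    with open(outdir / "ranked.rnk", "w") as fh:
        for g, s in sorted(ranked.items(), key=lambda kv: -kv[1]):
            fh.write(f"{g}\t{s:.6g}\n")
    gsea = expr_mod.gsea_preranked(
        ranked,
        set(inputs["effect_genes"]),
        gene_set_name="planted_effect_genes",
        n_perm=config.n_perm,
        min_size=config.min_size,
        max_size=config.max_size,
        seed=np.random.default_rng([config.seed, 7]),
    )
    collapsed_b = expr_mod.collapse_probes(
        bulk_b, reference_group=sorted(set(bulk_b.sample_groups.values()))[0]
    )
    sd_table, excluded = expr_mod.sd_heterogeneity(collapsed, collapsed_b)
    sd_table.to_csv(outdir / "sd_heterogeneity.tsv", sep="\t")
    bim_gene = inputs["bimodal_gene"]
    bim_values = collapsed.values.loc[bim_gene]
    threshold = expr_mod.bimodal_split(bim_values)
    anchor = inputs["effect_genes"][0]
    labels = expr_mod.split_by_mean(collapsed.values.loc[anchor])
    codiff = expr_mod.coexpression_diff(collapsed, labels)
    codiff.to_csv(outdir / "coexpression_diff.tsv", sep="\t")
    slope, intercept, r2 = expr_mod.linear_fit(
        collapsed.values.loc[anchor], collapsed.values.loc[inputs["effect_genes"][1]]
    )
    n_sig = int((de_df["q"] < 0.05).sum())
    logger.info("DE: %d/%d rows at q<0.05; GSEA ES=%.3f p=%.4g",
                n_sig, len(de_df), gsea.es, gsea.p_perm)
    return {
        "n_genes_tested": len(de_df),
        "n_de_q05": n_sig,
        "gsea": {
            "es": gsea.es,
            "nes": gsea.nes,
            "p_perm": gsea.p_perm,
            "set_size": gsea.set_size,
        },
        "n_sd_genes": len(sd_table),
        "n_sd_excluded": len(excluded),
        "bimodal_gene": bim_gene,
        "bimodal_threshold": threshold,
        "anchor_gene": anchor,
        "anchor_coexpression_diff_of_anchor": float(codiff[anchor]),
        "linear_fit": {"slope": slope, "intercept": intercept, "r2": r2},
    }


def _stage_scscore(config: RunConfig, inputs: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    cells = inputs["cells"]
    signature = set(inputs["sc_truth"]["signature_genes"])
    mean_scores = sc_mod.mean_module_score(cells, signature)
    auc_scores = sc_mod.auc_score(cells, signature, config.top_fraction)
    table = pd.DataFrame(
        {
            "mean_score": mean_scores.scores,
            "auc_score": auc_scores.scores,
            "cell_type": cells.cell_type[mean_scores.scores.index],
            "tumor": cells.tumor[mean_scores.scores.index],
        }
    )
    table.to_csv(outdir / "cell_scores.tsv", sep="\t")
    summary = {}
    for name, sc in (("mean", mean_scores), ("auc", auc_scores)):
        by = sc.by_group(cells.cell_type)
        by.to_csv(outdir / f"group_summary_{name}.tsv", sep="\t")
        test = sc_mod.groupwise_test(sc, cells.cell_type)
        test.pairwise.to_csv(outdir / f"pairwise_{name}.tsv", sep="\t", index=False)
        summary[name] = {
            "top_type_by_median": by["median"].idxmax(),
            "kruskal_h": test.h_statistic,
            "kruskal_p": test.p,
        }
        logger.info("%s score: top type %s, KW H=%.2f p=%.3g",
                    name, by["median"].idxmax(), test.h_statistic, test.p)
    summary["enriched_cell_type_truth"] = inputs["sc_truth"]["enriched_cell_type"]
    return summary


def _stage_cohort(config: RunConfig, inputs: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    calls = cohort_mod.call_arms(inputs["arm_scores"], config.arm_cutoff)
    calls.to_csv(outdir / "arm_calls.tsv", sep="\t")
    subgroup = inputs["subgroup"]
    freqs = {}
    for grp in sorted(subgroup.unique()):
        members = subgroup[subgroup == grp].index
        f = cohort_mod.alteration_frequency(calls, list(members))
        f.to_csv(outdir / f"frequency_{grp}.tsv", sep="\t")
        freqs[grp] = {
            "frac_1q_gain": float(f.loc["1q", "frac_gain"]),
            "frac_6q_loss": float(f.loc["6q", "frac_loss"]),
        }
    burden_table = cohort_mod.burden(calls, inputs["focal"])
    burden_table.to_csv(outdir / "burden.tsv", sep="\t")
    try:
        assoc = cohort_mod.burden_association(calls, "6q", "loss")
        assoc_summary = {
            "p": assoc.p,
            "n_marker": assoc.n_marker,
            "control_p": assoc.control_p,
        }
    except ValueError as exc:  # degenerate stratum in a tiny simulated cohort
        assoc_summary = {"error": str(exc)}
    surv = inputs["surv"]
    km = cohort_mod.km_logrank(surv)
    for g, curve in km.curves.items():
        curve.to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False)
    logger.info("arm cutoff +/-%.2f; log-rank chi2=%.2f p=%.3g",
                config.arm_cutoff, km.chi2, km.p)
    return {
        "alteration_frequencies": freqs,
        "burden_association_6q_loss": assoc_summary,
        "logrank": {"chi2": km.chi2, "p": km.p, "n_events": km.n_events},
    }
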