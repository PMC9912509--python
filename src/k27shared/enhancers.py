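"""ROSE-style super-enhancer calling and reciprocal enhancer sharing.

H3K27ac peaks within a stitching distance of each other (12.5 kb by
default) are merged into candidate enhancers whose signal is the sum of
their constituents.  Candidates are rank-ordered by total signal and the
super-enhancer cutoff is placed where the unit-scaled rank/signal curve's
slope first exceeds 1 — a deterministic discretization of the tangent-line
rule.  A cohort-specific enhancer is reclassified as shared when it
overlaps a called super enhancer in at least one sample of the other
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genome import GeneRegion, GenomicInterval, overlaps

__all__ = [
    "StitchedEnhancer",
    "SECallResult",
    "stitch",
    "call_super_enhancers",
    "reciprocal_share",
    "assign_enhancer_genes",
]


@dataclass(frozen=True)
class StitchedEnhancer:
    """A merged enhancer region with summed constituent signal."""

    interval: GenomicInterval
    signal: float
    n_constituents: int

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")
        if self.n_constituents < 1:
            raise ValueError("n_constituents must be >= 1")


@dataclass
class SECallResult:
    """Rank-ordered enhancers with the super-enhancer cutoff.

    ``ranked`` is sorted by ascending signal; ``super`` is the tail
    ``ranked[cutoff_index:]``, so every super-enhancer signal is at least
    as large as every non-super signal.
    """

    ranked: list[StitchedEnhancer]
    cutoff_index: int

    @property
    def super(self) -> list[StitchedEnhancer]:
        return self.ranked[self.cutoff_index :]


def stitch(
    peaks: list[GenomicInterval], gap_bp: int = 12_500
) -> list[StitchedEnhancer]:
    """Merge same-chromosome peaks whose gaps are <= ``gap_bp``, transitively.

    Merged signal is the sum of constituent peak scores (missing scores
    count as 0).  Output is sorted by (chrom, start) and non-overlapping.
    """
    if gap_bp < 0:
        raise ValueError(f"gap_bp must be >= 0, got {gap_bp}")
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    stitched: list[StitchedEnhancer] = []
    cur: dict | None = None
    for p in ordered:
        sig = p.score if p.score is not None else 0.0
        if (
            cur is not None
            and p.chrom == cur["chrom"]
            and p.start - cur["end"] <= gap_bp
        ):
            cur["end"] = max(cur["end"], p.end)
            cur["signal"] += sig
            cur["n"] += 1
        else:
            if cur is not None:
                stitched.append(_finish(cur))
            cur = {"chrom": p.chrom, "start": p.start, "end": p.end,
                   "signal": sig, "n": 1}
    if cur is not None:
        stitched.append(_finish(cur))
    return stitched


def _finish(cur: dict) -> StitchedEnhancer:
    return StitchedEnhancer(
        interval=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        signal=cur["signal"],
        n_constituents=cur["n"],
    )


def call_super_enhancers(stitched: list[StitchedEnhancer]) -> SECallResult:
    """Place the super-enhancer cutoff on the rank-ordered signal curve.

    Enhancers are sorted by ascending signal.  With ranks scaled to
    ``x_i = (i + 1) / n`` and signals scaled to ``y_i = s_i / max(s)``,
    the cutoff sits just after the first pair of consecutive points whose
    discrete slope exceeds 1; a boundary slope of exactly 1 does not yet
    qualify.  If no slope exceeds 1 (e.g. a perfectly linear curve) the
    super set is empty.  The partition is invariant to rescaling all
    signals by a positive constant.
    """
    if len(stitched) < 2:
        raise ValueError("need >= 2 stitched enhancers to place a cutoff")
    ranked = sorted(stitched, key=lambda e: e.signal)
    n = len(ranked)
    smax = ranked[-1].signal
    if smax == ranked[0].signal:
        warnings.warn(
            "all enhancer signals identical; degenerate rank curve, "
            "no super enhancers called",
            stacklevel=2,
        )
        return SECallResult(ranked=ranked, cutoff_index=n)
    cutoff = n  # no super enhancers unless a slope exceeds 1
    for i in range(n - 1):
        dy = (ranked[i + 1].signal - ranked[i].signal) / smax
        dx = 1.0 / n  # consecutive scaled ranks differ by 1/n
        if dy / dx > 1.0:
            cutoff = i + 1
            break
    return SECallResult(ranked=ranked, cutoff_index=cutoff)


def reciprocal_share(
    specific_a: list[GenomicInterval],
    se_calls_b: dict[str, SECallResult],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Promote A-specific enhancers that recur as super enhancers in cohort B.

    An enhancer is promoted to the shared list iff it overlaps (any bp) a
    *called super enhancer* in at least one sample of the other cohort;
    overlap with a merely stitched, non-super enhancer does not promote.
    Returns ``(promoted_shared, still_specific)`` — a disjoint, exhaustive
    partition preserving input order.
    """
    promoted: list[GenomicInterval] = []
    still: list[GenomicInterval] = []
    for enh in specific_a:
        hit = any(
            overlaps(enh, se.interval)
            for call in se_calls_b.values()
            for se in call.super
        )
        (promoted if hit else still).append(enh)
    return promoted, still


def assign_enhancer_genes(
    enhancers: list[GenomicInterval],
    regions: list[GeneRegion],
    mode: str = "nearest_tss",
) -> dict[GenomicInterval, str]:
    """Map each enhancer to the same-chromosome gene with the nearest TSS.

    Distance is measured from the enhancer midpoint to the gene's TSS
    (body start on '+', body end on '-').  Ties break lexicographically by
    gene_id.  Enhancers on chromosomes with no annotated gene are omitted
    from the mapping.
    """
    if mode != "nearest_tss":
        raise ValueError(f"unknown assignment mode {mode!r}")
    if not regions:
        raise ValueError("gene annotation must be non-empty")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in regions:
        tss = r.body.start if r.body.strand == "+" else r.body.end
        tss_by_chrom.setdefault(r.body.chrom, []).append((tss, r.gene_id))
    assignment: dict[GenomicInterval, str] = {}
    for enh in enhancers:
        candidates = tss_by_chrom.get(enh.chrom)
        if not candidates:
            continue
        mid = enh.midpoint
        assignment[enh] = min(
            candidates, key=lambda t: (abs(mid - t[0]), t[1])
        )[1]
    return assignment
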