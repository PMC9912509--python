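"""Consensus H3K27me3-retained gene calling across tumor cohorts.

In H3K27M diffuse midline gliomas and PFA ependymomas the repressive
H3K27me3 mark is globally depleted, but a subset of genes keeps it.  That
subset is identified per cohort by a cross-sample consensus: a gene counts
as supported by a sample when at least one of the sample's H3K27me3 peaks
overlaps the gene body or its 2-kb upstream promoter, and the gene is
called "retained" when it is supported by strictly more than two-thirds of
the cohort (7 of 9, or 5 of 6).  The per-cohort retained sets are then
compared to split genes into shared and subtype-specific groups.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from .genome import GeneRegion, GenomicInterval, overlaps

__all__ = [
    "PeakCohort",
    "ConsensusCall",
    "gene_support",
    "consensus_threshold",
    "call_retained",
    "consensus_table",
    "shared_and_specific",
]


@dataclass
class PeakCohort:
    """Per-sample peak sets for one tumor class.

    ``samples`` maps unique sample ids to that sample's peak intervals;
    a cohort has at least one sample.
    """

    tumor_class: str
    samples: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("cohort must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ConsensusCall:
    """Per-gene consensus summary: how many samples support the gene."""

    gene_id: str
    support_count: int
    n_samples: int
    retained: bool

    def __post_init__(self) -> None:
        if not 0 <= self.support_count <= self.n_samples:
            raise ValueError(
                f"support_count {self.support_count} outside [0, {self.n_samples}]"
            )


def _sample_supports(
    peaks_by_chrom: dict[str, list[GenomicInterval]], region: GeneRegion
) -> bool:
    """True iff any peak overlaps the gene body or promoter (binary per sample)."""
    for target in (region.body, region.promoter):
        for peak in peaks_by_chrom.get(target.chrom, ()):
            if overlaps(peak, target):
                return True
    return False


def gene_support(
    cohort: PeakCohort, regions: list[GeneRegion]
) -> dict[str, int]:
    """Count, per gene, the samples with >=1 peak over its body or promoter.

    Support is binary per sample: multiple peaks over the same gene in one
    sample contribute 1.  Samples with empty peak lists contribute 0
    everywhere.  Genes absent from ``regions`` are absent from the output.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    counts: dict[str, int] = {r.gene_id: 0 for r in regions}
    for peaks in cohort.samples.values():
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        for p in peaks:
            by_chrom[p.chrom].append(p)
        for region in regions:
            if _sample_supports(by_chrom, region):
                counts[region.gene_id] += 1
    return counts


def consensus_threshold(n_samples: int, fraction: float = 2.0 / 3.0) -> int:
    """Smallest integer count strictly exceeding ``fraction`` of the cohort.

    With the default two-thirds fraction this gives 7 for a 9-sample
    cohort and 5 for a 6-sample cohort.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return math.floor(fraction * n_samples) + 1


def consensus_table(
    cohort: PeakCohort,
    regions: list[GeneRegion],
    fraction: float = 2.0 / 3.0,
) -> list[ConsensusCall]:
    """Full per-gene consensus calls, sorted lexicographically by gene_id."""
    support = gene_support(cohort, regions)
    k = consensus_threshold(cohort.n_samples, fraction)
    return [
        ConsensusCall(
            gene_id=g,
            support_count=c,
            n_samples=cohort.n_samples,
            retained=c >= k,
        )
        for g, c in sorted(support.items())
    ]


def call_retained(
    cohort: PeakCohort,
    regions: list[GeneRegion],
    fraction: float = 2.0 / 3.0,
) -> set[str]:
    """Genes supported by strictly more than ``fraction`` of cohort samples."""
    return {c.gene_id for c in consensus_table(cohort, regions, fraction) if c.retained}


def shared_and_specific(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two retained-gene sets into (shared, A-only, B-only)."""
    shared = set_a & set_b
    return shared, set_a - shared, set_b - shared
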