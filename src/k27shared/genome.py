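"""Genomic interval arithmetic, gene/promoter modeling, and BED-family I/O.

Coordinates are 0-based half-open throughout (BED convention).  Abutting
intervals do not overlap, matching bedtools' default strict half-open
intersection.  Chromosome names are compared by exact string match; no
``chr`` prefix aliasing is performed unless requested explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty, compared verbatim).
    start : int
        0-based inclusive start, >= 0.
    end : int
        0-based exclusive end, > start.
    name : str, optional
        Feature name (BED column 4).
    score : float, optional
        Signal value in arbitrary units (BED column 5).
    strand : str, optional
        '+' or '-' (BED column 6).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene record with a strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"tx_end must exceed tx_start for {self.gene_id}: "
                f"[{self.tx_start}, {self.tx_end})"
            )
        if self.tx_start < 0:
            raise ValueError(f"tx_start must be >= 0 for {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on '+', tx_end on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass(frozen=True)
class GeneRegion:
    """A gene body plus its upstream promoter window."""

    gene_id: str
    body: GenomicInterval
    promoter: GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Any-bp overlap between two half-open intervals.

    True iff both intervals are on the same chromosome and share at least
    one base pair.  Abutting intervals ([100,200) vs [200,300)) do not
    overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def make_gene_regions(
    genes: Sequence[GeneModel], promoter_bp: int = 2000
) -> list[GeneRegion]:
    """Attach an upstream promoter window to each gene.

    The promoter is the ``promoter_bp`` window immediately upstream of the
    TSS: ``[tx_start - promoter_bp, tx_start)`` on the '+' strand and
    ``[tx_end, tx_end + promoter_bp)`` on the '-' strand.  Windows running
    past coordinate 0 are clamped with a warning.
    """
    if promoter_bp <= 0:
        raise ValueError(f"promoter_bp must be positive, got {promoter_bp}")
    regions = []
    for g in genes:
        body = GenomicInterval(g.chrom, g.tx_start, g.tx_end, strand=g.strand)
        if g.strand == "+":
            p_start = g.tx_start - promoter_bp
            if p_start < 0:
                warnings.warn(
                    f"promoter for {g.gene_id} truncated at chromosome start",
                    stacklevel=2,
                )
                p_start = 0
            promoter = GenomicInterval(g.chrom, p_start, g.tx_start, strand="+")
        else:
            promoter = GenomicInterval(
                g.chrom, g.tx_end, g.tx_end + promoter_bp, strand="-"
            )
        regions.append(GeneRegion(gene_id=g.gene_id, body=body, promoter=promoter))
    return regions


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, preserving file order.

    Columns beyond the third are optional and parsed as name, score and
    strand.  A '.' placeholder leaves the field unset.  Malformed lines
    raise with the 1-based line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score,
                                    strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED ('.' for unset optional fields)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name if iv.name is not None else ".",
                        score,
                        iv.strand if iv.strand is not None else ".",
                    ]
                )
                + "\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene annotation from a 6-column TSV or BED6 file.

    Two layouts are accepted and distinguished by the header / column
    content:

    * TSV with header ``gene_id  chrom  strand  start  end  [source]``
    * BED6 where column 4 (name) carries the gene_id

    Coordinates are 0-based half-open in both cases.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        genes = []
        with open(path) as fh2:
            header = fh2.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for lineno, raw in enumerate(fh2, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                try:
                    genes.append(
                        GeneModel(
                            gene_id=f[idx["gene_id"]],
                            chrom=f[idx["chrom"]],
                            strand=f[idx["strand"]],
                            tx_start=int(f[idx["start"]]),
                            tx_end=int(f[idx["end"]]),
                        )
                    )
                except (KeyError, ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return genes
    genes = []
    for iv in read_bed(path):
        if iv.name is None or iv.strand is None:
            raise ValueError(
                f"{path}: BED gene annotation requires name and strand columns"
            )
        genes.append(
            GeneModel(gene_id=iv.name, chrom=iv.chrom, strand=iv.strand,
                      tx_start=iv.start, tx_end=iv.end)
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as the 6-column TSV layout read by :func:`read_gene_table`."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\tsource\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t.\n"
            )
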