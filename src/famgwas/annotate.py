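"""Genic context of associated variants and conservation flagging.

A variant overlapping a gene is classified by its finest containing
feature (5'UTR, 3'UTR, exon with its ordinal in transcription order, or
intron); otherwise the nearest gene within a 10 kb window makes it
upstream or downstream, resolved by gene strand; otherwise it is
intergenic. Conservation comes from a user-supplied interval file
(half-open, 0-based, the standard interval-file convention).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneModel",
    "AnnotationRecord",
    "classify_variant",
    "conservation_flag",
    "read_gff3",
    "read_bed",
]

DEFAULT_WINDOW = 10_000


@dataclass
class GeneModel:
    """Gene with 1-based inclusive coordinates and optional sub-features."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)  # [(start, end), ...]
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: malformed strand {self.strand!r}"
            )
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")


@dataclass
class AnnotationRecord:
    """Genic classification of one variant."""

    variant_id: str
    genes: list = field(default_factory=list)
    position_class: str = "intergenic"
    distance: int | None = None
    conserved: bool = False


def _within(pos: int, start: int, end: int) -> bool:
    return start <= pos <= end


def _feature_class(pos: int, gene: GeneModel) -> str:
    """Finest feature containing ``pos`` inside the gene body."""
    for s, e in gene.utr5:
        if _within(pos, s, e):
            return "5'UTR"
    for s, e in gene.utr3:
        if _within(pos, s, e):
            return "3'UTR"
    exons = sorted(gene.exons, reverse=(gene.strand == "-"))
    for ordinal, (s, e) in enumerate(exons, start=1):
        if _within(pos, s, e):
            return f"exon({ordinal})"
    return "intron" if gene.exons else "exon(1)"


def classify_variant(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
    variant_id: str | None = None,
) -> AnnotationRecord:
    """Classify one variant against gene annotations.

    Overlapping genes are all reported (the position class comes from the
    first, in genome order). Without an overlap, the nearest gene within
    ``window`` bp decides upstream/downstream by its strand; otherwise
    the variant is intergenic.
    """
    variant_id = variant_id or f"{chrom}:{pos}"
    here = [g for g in genes if g.chrom == chrom]
    overlapping = [g for g in here if _within(pos, g.start, g.end)]
    if overlapping:
        overlapping.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return AnnotationRecord(
            variant_id=variant_id,
            genes=[g.gene_id for g in overlapping],
            position_class=_feature_class(pos, overlapping[0]),
            distance=0,
        )
    best, best_d = None, None
    for g in here:
        d = g.start - pos if pos < g.start else pos - g.end
        if d <= window and (best_d is None or d < best_d):
            best, best_d = g, d
    if best is None:
        return AnnotationRecord(variant_id=variant_id, position_class="intergenic")
    before_start = pos < best.start
    if best.strand == "+":
        side = "upstream" if before_start else "downstream"
    else:
        side = "downstream" if before_start else "upstream"
    return AnnotationRecord(
        variant_id=variant_id,
        genes=[best.gene_id],
        position_class=side,
        distance=int(best_d),
    )


def conservation_flag(position: int, intervals) -> bool:
    """True iff ``position`` falls in any half-open [start, end) interval.

    ``position`` is interpreted in the intervals' own 0-based system (a
    1-based variant position must be shifted by one before the lookup,
    as :func:`annotate_variants` does). Unsorted intervals are sorted
    internally with a warning.
    """
    ivals = [(int(s), int(e)) for s, e in intervals]
    if not ivals:
        return False
    starts = [s for s, _ in ivals]
    if any(starts[i] > starts[i + 1] for i in range(len(starts) - 1)):
        warnings.warn("conserved intervals unsorted; sorting internally")
        ivals.sort()
        starts = [s for s, _ in ivals]
    i = bisect_right(starts, position) - 1
    # earlier intervals may still cover the position when intervals overlap
    for j in range(i, -1, -1):
        s, e = ivals[j]
        if s <= position < e:
            return True
    return False


def annotate_variants(
    variants,
    genes: list[GeneModel],
    conserved: dict[str, list] | None = None,
    window: int = DEFAULT_WINDOW,
):
    """Classify a variant table (columns chrom, pos, id) against annotations.

    ``conserved`` maps chromosome -> list of 0-based half-open intervals.
    Returns a list of :class:`AnnotationRecord`.
    """
    conserved = conserved or {}
    out = []
    for row in variants.itertuples(index=False):
        rec = classify_variant(
            row.chrom, int(row.pos), genes, window=window, variant_id=row.id
        )
        rec.conserved = conservation_flag(
            int(row.pos) - 1, conserved.get(row.chrom, [])
        )
        out.append(rec)
    return out


def read_gff3(path) -> list[GeneModel]:
    """Load gene models (genes, exons, UTRs) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        for child in db.children(g):
            span = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(span)
            elif child.featuretype in ("five_prime_UTR", "5UTR"):
                utr5.append(span)
            elif child.featuretype in ("three_prime_UTR", "3UTR"):
                utr3.append(span)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                exons=sorted(set(exons)),
                utr5=sorted(set(utr5)),
                utr3=sorted(set(utr3)),
            )
        )
    return genes


def read_bed(path) -> dict[str, list]:
    """Read a BED interval file into chrom -> [(start, end), ...] (0-based)."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.setdefault(chrom, []).append((int(start), int(end)))
    for chrom in out:
        out[chrom].sort()
    return out
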