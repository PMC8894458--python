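"""Candidate pseudoexon calling from merged splice-junction evidence.

The procedure: pool junction read counts across all samples; keep junctions
with strictly more than ``min_total_reads`` pooled unique reads (default 12;
an 8-read variant compensates for shorter reads); pair every retained
junction end with every retained junction start on the same contig and
strand such that the enclosed interval — a putative cassette exon of length
``J2.start - J1.end - 1`` — is between ``min_gap`` and ``max_gap`` bp
(12–512 by default); discard any interval that overlaps an annotated exon.
Survivors are candidate pseudoexons, reported with 5 bp flanked sequence.

"Apart" is interpreted as the candidate-exon length ``J2.start - J1.end - 1``;
the flanking-intron convention then gives exon = [J1.end+1, J2.start-1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pseudoex.io import (
    AnnotationModel,
    GenomeAccessor,
    GenomicInterval,
    JunctionRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the calling procedure.

    ``min_total_reads`` is a strictly-greater threshold on the pooled
    unique-read count (12 by default; 8 for short-read libraries).
    ``min_gap``/``max_gap`` bound the candidate-exon length in bp.
    """

    min_total_reads: int = 12
    min_gap: int = 12
    max_gap: int = 512
    flank: int = 5

    ALT_MIN_TOTAL_READS = 8  # short-read variant

    def __post_init__(self) -> None:
        if not (0 < self.min_gap <= self.max_gap):
            raise ValueError("require 0 < min_gap <= max_gap")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class MergedJunction:
    """A junction pooled over samples, with the summed unique-read count."""

    chrom: str
    start: int
    end: int
    strand: str
    total_reads: int


@dataclass
class CandidateExon:
    interval: GenomicInterval
    upstream_intron: GenomicInterval
    downstream_intron: GenomicInterval
    upstream_support: int
    downstream_support: int
    genes: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"


def merge_and_filter_junctions(
    records: Iterable[JunctionRecord], params: CallerParams | None = None
) -> list[MergedJunction]:
    """Pool unique-read counts by (chrom, start, end, strand) and filter.

    Junctions with undefined strand are dropped (pairing requires a definite
    strand); only pooled totals strictly greater than
    ``params.min_total_reads`` survive.
    """
    params = params or CallerParams()
    totals: dict[tuple[str, int, int, str], int] = {}
    for r in records:
        if r.strand == ".":
            continue
        key = (r.chrom, r.start, r.end, r.strand)
        totals[key] = totals.get(key, 0) + r.unique_reads
    merged = [
        MergedJunction(c, s, e, st, n)
        for (c, s, e, st), n in totals.items()
        if n > params.min_total_reads
    ]
    merged.sort(key=lambda j: (j.chrom, j.start, j.end, j.strand))
    return merged


def enumerate_candidates(
    merged: Sequence[MergedJunction], params: CallerParams | None = None
) -> list[CandidateExon]:
    """All intron-end/intron-start pairs enclosing a plausible exon.

    For every ordered pair (J1, J2) on the same contig and strand with
    ``J2.start > J1.end``, emit the interval [J1.end+1, J2.start-1] iff its
    length lies in [min_gap, max_gap]. A junction never pairs with itself.
    Candidates are deduplicated by coordinate id, keeping the best-supported
    flanking pair, and sorted by (chrom, start, end, strand).
    """
    params = params or CallerParams()
    by_group: dict[tuple[str, str], list[MergedJunction]] = {}
    for j in merged:
        by_group.setdefault((j.chrom, j.strand), []).append(j)

    best: dict[str, CandidateExon] = {}
    for (chrom, strand), juncs in by_group.items():
        ends = sorted(juncs, key=lambda j: j.end)
        starts = sorted(juncs, key=lambda j: j.start)
        for j1 in ends:
            # exon length = j2.start - j1.end - 1 in [min_gap, max_gap]
            lo = j1.end + params.min_gap + 1
            hi = j1.end + params.max_gap + 1
            for j2 in starts:
                if j2.start < lo or j2.start > hi:
                    continue
                if j2 is j1:
                    continue
                cand = CandidateExon(
                    interval=GenomicInterval(chrom, j1.end + 1, j2.start - 1, strand),
                    upstream_intron=GenomicInterval(chrom, j1.start, j1.end, strand),
                    downstream_intron=GenomicInterval(chrom, j2.start, j2.end, strand),
                    upstream_support=j1.total_reads,
                    downstream_support=j2.total_reads,
                )
                prev = best.get(cand.id)
                if prev is None or (
                    cand.upstream_support + cand.downstream_support,
                    -cand.upstream_intron.start,
                    cand.downstream_intron.end,
                ) > (
                    prev.upstream_support + prev.downstream_support,
                    -prev.upstream_intron.start,
                    prev.downstream_intron.end,
                ):
                    best[cand.id] = cand
    out = list(best.values())
    out.sort(key=_sort_key)
    return out


def _sort_key(c: CandidateExon):
    iv = c.interval
    return (iv.chrom, iv.start, iv.end, iv.strand)


def subtract_annotation(
    candidates: Sequence[CandidateExon], annotation: AnnotationModel
) -> list[CandidateExon]:
    """Keep only candidates overlapping no annotated exon by >= 1 bp.

    Overlap is strand-agnostic: an exon annotated on either strand removes
    the candidate.
    """
    return [c for c in candidates if not annotation.exons_overlapping(c.interval)]


def map_to_genes(
    candidates: Sequence[CandidateExon], annotation: AnnotationModel
) -> list[CandidateExon]:
    """Tag each candidate with the symbols of genes whose span overlaps it.

    Candidates overlapping no gene get an empty tag list (intergenic).
    Multiple overlapping genes are all retained, in deterministic order.
    """
    for c in candidates:
        c.genes = [g.symbol for g in annotation.genes_overlapping(c.interval)]
    return list(candidates)


def extract_candidate_sequence(
    candidate: CandidateExon, genome: GenomeAccessor, flank: int = 5
) -> tuple[str, str]:
    """Flanked candidate sequence: (genomic orientation, strand orientation).

    Length is exon length + 2*flank. Raises ``IndexError`` when the flank
    extends past the contig boundary.
    """
    iv = candidate.interval
    genomic = genome.fetch(iv.chrom, iv.start - flank, iv.end + flank)
    oriented = reverse_complement(genomic) if iv.strand == "-" else genomic
    return genomic, oriented


def call_pseudoexons(
    records: Iterable[JunctionRecord],
    annotation: AnnotationModel,
    params: CallerParams | None = None,
) -> list[CandidateExon]:
    """Full calling pipeline: merge+filter, pair, subtract annotation, map genes."""
    params = params or CallerParams()
    merged = merge_and_filter_junctions(records, params)
    logger.info("merged junctions passing read filter: %d", len(merged))
    cands = enumerate_candidates(merged, params)
    logger.info("candidate intervals before annotation subtraction: %d", len(cands))
    cands = subtract_annotation(cands, annotation)
    logger.info("candidates after annotation subtraction: %d", len(cands))
    return map_to_genes(cands, annotation)


def write_candidates_bed(candidates: Sequence[CandidateExon], path: str | Path) -> None:
    """BED6 output; 1-based inclusive internal coordinates become 0-based half-open."""
    with open(path, "w") as fh:
        for c in candidates:
            iv = c.interval
            score = min(1000, c.upstream_support + c.downstream_support)
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{c.id}\t{score}\t{iv.strand}\n"
            )
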