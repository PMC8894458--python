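"""Coding consequences of pseudoexon inclusion; natural inclusion rates.

A candidate spliced into a transcript inserts one exon strictly inside an
intron. If the insertion lies within the CDS, the spliced CDS is translated
in the original reading frame (standard nuclear code): an insertion whose
length is not a multiple of 3 shifts the downstream frame (frameshift), and
any stop codon encountered is attributed to the pseudoexon when its first
base lies inside the pseudoexon interval (codons may straddle junctions),
otherwise to downstream exons. The CDS convention is Ensembl's: the
annotated CDS excludes the terminal stop codon, so a wild-type transcript
reports zero stops.

Natural inclusion rates over a cross-sample junction database: with
supporting-sample sets S_up, S_dn for the two inclusion junctions and
S_excl for the exclusion (canonical) junction,

    rate = 100 * |S_up & S_dn| / |S_excl | (S_up & S_dn)|

so the rate is always within [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio.Seq import Seq

from pseudoex.io import GenomeAccessor, GenomicInterval, TranscriptRecord, reverse_complement
from pseudoex.caller import CandidateExon

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """Ordered exon structure with an optional genomic CDS span."""

    id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None  # genomic, 1-based inclusive, excludes stop codon
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping exons in transcript {self.id}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not any(e.start <= self.cds_start <= e.end for e in self.exons):
                raise ValueError("CDS start not inside an exon")
            if not any(e.start <= self.cds_end <= e.end for e in self.exons):
                raise ValueError("CDS end not inside an exon")

    @classmethod
    def from_record(cls, rec: TranscriptRecord) -> "TranscriptModel":
        return cls(
            id=rec.transcript_id,
            chrom=rec.chrom,
            strand=rec.strand,
            exons=list(rec.exons),
            cds_start=rec.cds_start,
            cds_end=rec.cds_end,
        )


@dataclass
class ConsequenceReport:
    frameshift: bool
    pseudoexon_length: int
    stops_in_pseudoexon: int
    stops_downstream: int
    first_stop_codon_offset: int | None  # codon index from pseudoexon start
    coding_insertion: bool = True


def splice_in(transcript: TranscriptModel, candidate: CandidateExon) -> TranscriptModel:
    """Insert the candidate as a new exon; it must lie strictly inside an intron."""
    iv = candidate.interval
    if iv.chrom != transcript.chrom:
        raise ValueError("candidate on a different contig than the transcript")
    exons = transcript.exons
    # strictly inside: at least one intronic base on each side of the insert
    inside_intron = any(
        a.end + 1 < iv.start and iv.end < b.start - 1
        for a, b in zip(exons, exons[1:])
    )
    if not inside_intron:
        raise ValueError(
            f"candidate {candidate.id} does not lie strictly inside an intron "
            f"of transcript {transcript.id}"
        )
    return TranscriptModel(
        id=f"{transcript.id}+{candidate.id}",
        chrom=transcript.chrom,
        strand=transcript.strand,
        exons=exons + [replace(iv, strand=transcript.strand)],
        cds_start=transcript.cds_start,
        cds_end=transcript.cds_end,
    )


def _cds_sequence(
    model: TranscriptModel, genome: GenomeAccessor
) -> tuple[str, list[int]]:
    """Spliced CDS sequence and genomic position of each base, both in
    translation (5'->3') order."""
    segs: list[str] = []
    positions: list[int] = []
    for ex in model.exons:
        a = max(ex.start, model.cds_start)
        b = min(ex.end, model.cds_end)
        if a <= b:
            segs.append(genome.fetch(model.chrom, a, b))
            positions.extend(range(a, b + 1))
    seq = "".join(segs)
    if model.strand == "-":
        seq = reverse_complement(seq)
        positions = positions[::-1]
    return seq, positions


def coding_consequence(
    spliced: TranscriptModel,
    pseudoexon: GenomicInterval,
    genome: GenomeAccessor,
) -> ConsequenceReport:
    """Translate the spliced CDS in the original frame and locate stops.

    Reports the frameshift flag (insertion length mod 3 != 0), the number
    of stop codons whose first base lies inside the pseudoexon, and stops
    in downstream exons out to the end of the original CDS span.
    """
    if spliced.cds_start is None:
        raise ValueError(f"transcript {spliced.id} has no CDS")
    length = pseudoexon.length
    in_cds = (
        pseudoexon.start > spliced.cds_start and pseudoexon.end < spliced.cds_end
    )
    if not in_cds:
        return ConsequenceReport(
            frameshift=False,
            pseudoexon_length=length,
            stops_in_pseudoexon=0,
            stops_downstream=0,
            first_stop_codon_offset=None,
            coding_insertion=False,
        )

    seq, positions = _cds_sequence(spliced, genome)

    px = set(range(pseudoexon.start, pseudoexon.end + 1))
    # first CDS index (translation order) at/after the pseudoexon start
    px_first_idx = next(i for i, p in enumerate(positions) if p in px)

    stops_in = 0
    stops_down = 0
    first_offset = None
    n_codons = len(seq) // 3
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        if codon not in STOP_CODONS:
            continue
        first_base_pos = positions[3 * ci]
        if first_base_pos in px:
            stops_in += 1
            if first_offset is None:
                first_offset = ci - px_first_idx // 3
        elif 3 * ci >= px_first_idx:
            stops_down += 1
            if first_offset is None:
                first_offset = ci - px_first_idx // 3
    return ConsequenceReport(
        frameshift=(length % 3 != 0),
        pseudoexon_length=length,
        stops_in_pseudoexon=stops_in,
        stops_downstream=stops_down,
        first_stop_codon_offset=first_offset,
        coding_insertion=True,
    )


def translate_cds(model: TranscriptModel, genome: GenomeAccessor) -> str:
    """Amino-acid sequence of the model's CDS (standard code, '*' at stops)."""
    seq, _ = _cds_sequence(model, genome)
    trimmed = seq[: 3 * (len(seq) // 3)]
    return str(Seq(trimmed).translate())


def inclusion_rate(
    database: Mapping[tuple[int, int], Sequence[str]],
    upstream: tuple[int, int],
    downstream: tuple[int, int],
    exclusion: tuple[int, int],
) -> float:
    """Percentage of samples including the cassette exon naturally.

    ``database`` maps (intron start, intron end) to the ids of samples
    supporting that junction. Samples supporting both inclusion junctions
    are counted as including; the denominator is their union with samples
    supporting the exclusion junction.
    """
    s_up = set(database.get(tuple(upstream), ()))
    s_dn = set(database.get(tuple(downstream), ()))
    s_excl = set(database.get(tuple(exclusion), ()))
    incl = s_up & s_dn
    denom = s_excl | incl
    if not denom:
        raise ValueError(
            "inclusion rate undefined: no sample supports the exclusion "
            "junction or both inclusion junctions"
        )
    return 100.0 * len(incl) / len(denom)
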