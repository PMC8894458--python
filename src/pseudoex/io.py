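"""On-disk formats and coordinate conventions.

Junction tables use the STAR ``SJ.out.tab`` dialect: nine tab-separated
columns (chrom, intron start, intron end, strand code, intron motif,
annotated flag, unique reads, multi-mapping reads, max overhang), with
1-based inclusive intron coordinates. Strand codes: 0 = undefined,
1 = '+', 2 = '-'. Only the unique-read column supports junctions here;
multi-mapping counts are read but discarded.

Annotations come from Ensembl-dialect GTF (parsed with gffutils into an
in-memory database), genomes from FASTA via pyfaidx. The convention that
ties everything together: for two junctions flanking a cassette exon,
``upstream.end + 1 == exon.start`` and ``downstream.start - 1 == exon.end``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from intervaltree import IntervalTree
from pyfaidx import Fasta

_STRAND_FROM_CODE = {"0": ".", "1": "+", "2": "-"}
_CODE_FROM_STRAND = {".": "0", "+": "1", "-": "2"}


@dataclass(frozen=True)
class JunctionRecord:
    """One observed intron in one sample.

    ``start``/``end`` are the 1-based positions of the first and last
    intronic base. ``strand`` is '+', '-' or '.' (undefined).
    """

    chrom: str
    start: int
    end: int
    strand: str
    unique_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.unique_reads < 0:
            raise ValueError(f"negative read count {self.unique_reads}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None


class AnnotationModel:
    """Genes, transcripts with ordered exon lists, and an exon overlap index.

    The exon index is an interval tree per contig over every exon feature of
    every transcript; queries are strand-agnostic.
    """

    def __init__(
        self,
        genes: dict[str, GeneRecord],
        transcripts: dict[str, TranscriptRecord],
    ):
        self.genes = genes
        self.transcripts = transcripts
        self._exon_trees: dict[str, IntervalTree] = {}
        for tx in transcripts.values():
            tree = self._exon_trees.setdefault(tx.chrom, IntervalTree())
            for ex in tx.exons:
                # interval tree is half-open; store [start, end+1)
                tree.addi(ex.start, ex.end + 1, (tx.transcript_id, ex))

    def exons_overlapping(self, interval: GenomicInterval) -> list[GenomicInterval]:
        """All annotated exons overlapping ``interval`` by >= 1 bp."""
        tree = self._exon_trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data[1] for hit in tree.overlap(interval.start, interval.end + 1)]

    def genes_overlapping(self, interval: GenomicInterval) -> list[GeneRecord]:
        """Genes whose transcription span overlaps ``interval``, sorted by symbol."""
        hits = [
            g
            for g in self.genes.values()
            if g.chrom == interval.chrom
            and g.start <= interval.end
            and interval.start <= g.end
        ]
        return sorted(hits, key=lambda g: (g.symbol, g.gene_id))


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    condition: str
    replicate: int
    junction_path: str | None = None
    library_size: int | None = None


class JunctionParseError(ValueError):
    pass


def read_junction_table(path: str | Path, sample_id: str = "") -> list[JunctionRecord]:
    """Parse a STAR ``SJ.out.tab``-dialect file into junction records.

    Raises :class:`JunctionParseError` naming the offending line on a
    malformed row, and ``ValueError`` on negative counts.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 7:
                raise JunctionParseError(
                    f"{path}: line {lineno}: expected >=7 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = _STRAND_FROM_CODE[fields[3]]
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise JunctionParseError(
                    f"{path}: line {lineno}: cannot parse row: {exc}"
                ) from exc
            if unique < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative unique-read count {unique}"
                )
            records.append(
                JunctionRecord(chrom, start, end, strand, unique, sample_id)
            )
    return records


def write_junction_table(records: Iterable[JunctionRecord], path: str | Path) -> None:
    """Write records back in the 9-column dialect (motif/annotated/multi = 0)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{_CODE_FROM_STRAND[r.strand]}"
                f"\t0\t0\t{r.unique_reads}\t0\t0\n"
            )


def read_annotation(path: str | Path) -> AnnotationModel:
    """Load a GTF into an :class:`AnnotationModel` via gffutils (in memory)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneRecord] = {}
    transcripts: dict[str, TranscriptRecord] = {}

    for feat in db.features_of_type("gene"):
        gid = _required_attr(feat, "gene_id")
        symbol = feat.attributes.get("gene_name", [gid])[0]
        genes[gid] = GeneRecord(gid, symbol, feat.seqid, feat.strand, feat.start, feat.end)

    for feat in db.features_of_type("transcript"):
        tid = _required_attr(feat, "transcript_id")
        gid = _required_attr(feat, "gene_id")
        transcripts[tid] = TranscriptRecord(tid, gid, feat.seqid, feat.strand)

    for feat in db.features_of_type("exon"):
        tid = _required_attr(feat, "transcript_id")
        gid = _required_attr(feat, "gene_id")
        if feat.end < feat.start:
            raise ValueError(f"exon with end < start at {feat.seqid}:{feat.start}")
        tx = transcripts.setdefault(
            tid, TranscriptRecord(tid, gid, feat.seqid, feat.strand)
        )
        tx.exons.append(GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand))

    for feat in db.features_of_type("CDS"):
        tid = _required_attr(feat, "transcript_id")
        tx = transcripts[tid]
        tx.cds_start = feat.start if tx.cds_start is None else min(tx.cds_start, feat.start)
        tx.cds_end = feat.end if tx.cds_end is None else max(tx.cds_end, feat.end)

    for tx in transcripts.values():
        tx.exons.sort(key=lambda e: e.start)
        for a, b in zip(tx.exons, tx.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping exons within transcript {tx.transcript_id}"
                )
        # derive a gene record if the GTF carries no gene features
        if tx.gene_id not in genes and tx.exons:
            genes[tx.gene_id] = GeneRecord(
                tx.gene_id,
                tx.gene_id,
                tx.chrom,
                tx.strand,
                tx.exons[0].start,
                tx.exons[-1].end,
            )

    return AnnotationModel(genes, transcripts)


def _required_attr(feat, name: str) -> str:
    vals = feat.attributes.get(name)
    if not vals:
        raise ValueError(f"feature at {feat.seqid}:{feat.start} lacks {name}")
    return vals[0]


class GenomeAccessor:
    """1-based inclusive fetch over an indexed FASTA."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``[start, end]``, 1-based inclusive."""
        if chrom not in self._fasta:
            raise KeyError(f"unknown contig {chrom!r}")
        n = len(self._fasta[chrom])
        if start < 1 or end > n or start > end:
            raise IndexError(
                f"fetch {chrom}:{start}-{end} out of bounds (contig length {n})"
            )
        return str(self._fasta[chrom][start - 1 : end])


class InMemoryGenome:
    """Dict-backed sequence accessor with the same 1-based fetch contract."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {k: v.upper() for k, v in sequences.items()}

    def contigs(self) -> list[str]:
        return list(self._seqs)

    def contig_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"fetch {chrom}:{start}-{end} out of bounds (contig length {len(seq)})"
            )
        return seq[start - 1 : end]


def read_genome(path: str | Path) -> GenomeAccessor:
    return GenomeAccessor(path)


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    """Sample sheet TSV: sample_id, condition, replicate[, junction_path[, library_size]]."""
    designs: list[SampleDesign] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "condition", "replicate"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        base = Path(path).parent
        for row in reader:
            jp = row.get("junction_path") or None
            if jp is not None and not Path(jp).is_absolute():
                jp = str(base / jp)  # relative to the sheet's directory
            designs.append(
                SampleDesign(
                    sample_id=row["sample_id"],
                    condition=row["condition"],
                    replicate=int(row["replicate"]),
                    junction_path=jp,
                    library_size=int(row["library_size"])
                    if row.get("library_size")
                    else None,
                )
            )
    seen = [d.sample_id for d in designs]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate sample_id in sample sheet")
    return designs


def write_sample_sheet(designs: Iterable[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\treplicate\tjunction_path\tlibrary_size\n")
        for d in designs:
            fh.write(
                f"{d.sample_id}\t{d.condition}\t{d.replicate}\t"
                f"{d.junction_path or ''}\t{d.library_size or ''}\n"
            )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
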