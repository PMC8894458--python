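"""Quantification of candidates and annotated features; normalization.

Counting is fragment-based: a sequenced fragment (read pair) contributes at
most once per feature, and any overlap of >= 1 bp counts. When per-sample
fragment intervals are unavailable, a junction-support fallback scores each
candidate per sample as min(upstream-junction reads, downstream-junction
reads) — the number of fragments that can be attributed unambiguously to
the included isoform.

Library-size normalization offers both total-count scaling (CPM/RPKM) and
median-of-ratios size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from pseudoex.io import AnnotationModel, GenomicInterval, JunctionRecord, SampleDesign
from pseudoex.caller import CandidateExon


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with library sizes."""

    counts: pd.DataFrame  # rows = feature ids, columns = sample ids
    library_sizes: pd.Series  # indexed by sample id
    feature_lengths: pd.Series | None = None  # bp, indexed by feature id
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes[self.library_sizes.isna()].index.tolist()
            raise ValueError(f"missing library sizes for samples {missing}")

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")


@dataclass(frozen=True)
class ExonBin:
    gene_id: str
    interval: GenomicInterval
    rank: int  # 1-based, 5'->3' in gene orientation

    @property
    def id(self) -> str:
        return f"{self.gene_id}:bin{self.rank}"


def coverage_counts(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    candidates: Sequence[CandidateExon],
    designs: Sequence[SampleDesign],
) -> CountMatrix:
    """Count fragments overlapping each candidate by >= 1 bp, per sample.

    ``fragments`` maps sample_id -> fragment intervals. Library size is the
    total number of fragments imported for the sample.
    """
    unknown = set(fragments) - {d.sample_id for d in designs}
    if unknown:
        raise ValueError(f"samples not in design: {sorted(unknown)}")
    sample_ids = [d.sample_id for d in designs]
    trees: dict[str, IntervalTree] = {}
    for i, c in enumerate(candidates):
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end + 1, i
        )
    mat = np.zeros((len(candidates), len(sample_ids)), dtype=int)
    libsizes = {}
    for j, sid in enumerate(sample_ids):
        frags = fragments.get(sid, [])
        libsizes[sid] = len(frags)
        for fr in frags:
            tree = trees.get(fr.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(fr.start, fr.end + 1):
                mat[hit.data, j] += 1
    counts = pd.DataFrame(mat, index=[c.id for c in candidates], columns=sample_ids)
    lengths = pd.Series(
        [c.interval.length for c in candidates], index=counts.index, dtype=float
    )
    return CountMatrix(
        counts,
        pd.Series(libsizes),
        feature_lengths=lengths,
        meta={"mode": "fragment_coverage"},
    )


def junction_fallback_counts(
    records: Iterable[JunctionRecord],
    candidates: Sequence[CandidateExon],
    designs: Sequence[SampleDesign],
) -> CountMatrix:
    """Fallback quantification from per-sample flanking-junction support.

    Per sample, a candidate's count is min(upstream reads, downstream reads)
    of its two flanking inclusion junctions. Library size is taken from the
    sample sheet when present, else the sample's total unique junction reads.
    """
    sample_ids = [d.sample_id for d in designs]
    known = set(sample_ids)
    per_sample: dict[str, dict[tuple[str, int, int, str], int]] = {
        s: {} for s in sample_ids
    }
    totals = dict.fromkeys(sample_ids, 0)
    for r in records:
        if r.sample_id not in known:
            raise ValueError(f"sample {r.sample_id!r} not in design")
        key = (r.chrom, r.start, r.end, r.strand)
        d = per_sample[r.sample_id]
        d[key] = d.get(key, 0) + r.unique_reads
        totals[r.sample_id] += r.unique_reads

    mat = np.zeros((len(candidates), len(sample_ids)), dtype=int)
    for i, c in enumerate(candidates):
        up = c.upstream_intron
        dn = c.downstream_intron
        ukey = (up.chrom, up.start, up.end, up.strand)
        dkey = (dn.chrom, dn.start, dn.end, dn.strand)
        for j, sid in enumerate(sample_ids):
            d = per_sample[sid]
            mat[i, j] = min(d.get(ukey, 0), d.get(dkey, 0))
    counts = pd.DataFrame(mat, index=[c.id for c in candidates], columns=sample_ids)
    libsizes = pd.Series(
        {
            d.sample_id: d.library_size
            if d.library_size is not None
            else totals[d.sample_id]
            for d in designs
        }
    )
    lengths = pd.Series(
        [c.interval.length for c in candidates], index=counts.index, dtype=float
    )
    return CountMatrix(
        counts, libsizes, feature_lengths=lengths, meta={"mode": "junction_fallback"}
    )


def disjoint_exon_bins(annotation: AnnotationModel, gene_id: str) -> list[ExonBin]:
    """Non-overlapping exon bins covering the union of a gene's exons.

    Bin boundaries fall at every distinct exon start/end across the gene's
    transcripts; ranks run 5'->3' in gene orientation (rank 1 is the
    rightmost bin for a minus-strand gene).
    """
    if gene_id not in annotation.genes:
        raise KeyError(f"unknown gene {gene_id!r}")
    gene = annotation.genes[gene_id]
    exons = [
        ex
        for tx in annotation.transcripts.values()
        if tx.gene_id == gene_id
        for ex in tx.exons
    ]
    if not exons:
        return []
    # breakpoints at every exon start and end+1 (half-open arithmetic);
    # each covered segment between consecutive breakpoints is one bin
    points = sorted({p for ex in exons for p in (ex.start, ex.end + 1)})
    covered = []
    for a, b in zip(points, points[1:]):
        if any(ex.start <= a and b - 1 <= ex.end for ex in exons):
            covered.append((a, b - 1))
    n = len(covered)
    bins = []
    for i, (a, b) in enumerate(covered):
        rank = i + 1 if gene.strand != "-" else n - i
        bins.append(
            ExonBin(gene_id, GenomicInterval(gene.chrom, a, b, gene.strand), rank)
        )
    return bins


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per-feature geometric means are computed over features with positive
    counts in every sample; each sample's factor is the median over those
    features of count / geometric mean.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in all samples; "
            "fall back to library-size normalization"
        )
    sub = arr[all_pos]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.median(np.exp(np.log(sub) - log_geomean[:, None]), axis=0)
    return pd.Series(factors, index=df.columns, name="size_factor")


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped fragments."""
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.counts / lib * 1e6


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments."""
    if counts.feature_lengths is None:
        raise ValueError("feature lengths required for RPKM")
    lengths = counts.feature_lengths.reindex(counts.counts.index).to_numpy(dtype=float)
    if (lengths <= 0).any() or np.isnan(lengths).any():
        raise ValueError("feature lengths must be positive")
    return cpm(counts).div(lengths / 1e3, axis=0)


def expression_filter(
    counts: CountMatrix, threshold_rpkm: float = 0.5, min_samples: int = 2
) -> list[str]:
    """Features with RPKM strictly above threshold in >= min_samples samples."""
    r = rpkm(counts)
    keep = (r > threshold_rpkm).sum(axis=1) >= min_samples
    return list(r.index[keep])
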