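"""Junction merging, pairing, annotation subtraction and sequence extraction."""

import numpy as np
import pytest

from pseudoex.io import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    InMemoryGenome,
    JunctionRecord,
    TranscriptRecord,
    reverse_complement,
)
from pseudoex.caller import (
    CallerParams,
    CandidateExon,
    call_pseudoexons,
    enumerate_candidates,
    extract_candidate_sequence,
    map_to_genes,
    merge_and_filter_junctions,
    subtract_annotation,
    write_candidates_bed,
)


def _records_from_counts(counts):
    return [
        JunctionRecord("chr1", 100, 200, "+", c, f"s{i}") for i, c in enumerate(counts)
    ]


class TestMergeAndFilter:
    def test_strictly_greater_than_threshold(self):
        """Pooled totals of 13 survive the >12 filter; totals of 12 do not."""
        kept = merge_and_filter_junctions(_records_from_counts([2, 2, 2, 2, 2, 3]))
        assert len(kept) == 1 and kept[0].total_reads == 13
        dropped = merge_and_filter_junctions(_records_from_counts([2, 2, 2, 2, 2, 2]))
        assert dropped == []

    def test_eight_read_variant(self):
        params = CallerParams(min_total_reads=CallerParams.ALT_MIN_TOTAL_READS)
        assert merge_and_filter_junctions(_records_from_counts([9]), params)
        assert not merge_and_filter_junctions(_records_from_counts([8]), params)

    def test_opposite_strands_stay_distinct(self):
        recs = [
            JunctionRecord("chr1", 100, 200, "+", 20, "a"),
            JunctionRecord("chr1", 100, 200, "-", 20, "a"),
        ]
        assert len(merge_and_filter_junctions(recs)) == 2

    def test_unknown_strand_dropped(self):
        recs = [JunctionRecord("chr1", 100, 200, ".", 99, "a")]
        assert merge_and_filter_junctions(recs) == []

    def test_totals_match_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        keys = [
            ("chr1", int(s), int(s) + int(l), st)
            for s, l, st in zip(
                rng.integers(1, 50, 40), rng.integers(20, 60, 40),
                rng.choice(["+", "-"], 40),
            )
        ]
        recs = [
            JunctionRecord(*keys[int(i)], int(c), f"s{j}")
            for j, (i, c) in enumerate(
                zip(rng.integers(0, len(keys), 120), rng.integers(0, 10, 120))
            )
        ]
        merged = merge_and_filter_junctions(recs, CallerParams(min_total_reads=0))
        for m in merged:
            oracle = 0
            for r in recs:  # hash-free nested loop
                if (r.chrom, r.start, r.end, r.strand) == (m.chrom, m.start, m.end, m.strand):
                    oracle += r.unique_reads
            assert m.total_reads == oracle


class TestEnumerate:
    def test_htt_worked_example(self, htt_junctions):
        """The three printed HTT junctions yield exactly one candidate exon."""
        merged = merge_and_filter_junctions(htt_junctions)
        cands = enumerate_candidates(merged)
        assert len(cands) == 1
        iv = cands[0].interval
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr4", 3213622, 3213736, "+")
        assert iv.length == 115

    @pytest.mark.parametrize("gap,expected", [(11, 0), (12, 1), (512, 1), (513, 0)])
    def test_gap_boundaries(self, gap, expected):
        recs = [
            JunctionRecord("chr1", 50, 100, "+", 20, "a"),
            JunctionRecord("chr1", 100 + gap + 1, 2000, "+", 20, "a"),
        ]
        cands = enumerate_candidates(merge_and_filter_junctions(recs))
        assert len(cands) == expected
        if expected:
            assert cands[0].interval.length == gap

    def test_different_strands_never_pair(self):
        recs = [
            JunctionRecord("chr1", 50, 100, "+", 20, "a"),
            JunctionRecord("chr1", 151, 300, "-", 20, "a"),
        ]
        assert enumerate_candidates(merge_and_filter_junctions(recs)) == []

    def test_different_contigs_never_pair(self):
        recs = [
            JunctionRecord("chr1", 50, 100, "+", 20, "a"),
            JunctionRecord("chr2", 151, 300, "+", 20, "a"),
        ]
        assert enumerate_candidates(merge_and_filter_junctions(recs)) == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        recs = [
            JunctionRecord(
                rng.choice(["chr1", "chr2"]),
                int(s),
                int(s) + int(l),
                rng.choice(["+", "-"]),
                20,
                "a",
            )
            for s, l in zip(rng.integers(1, 3000, 50), rng.integers(50, 800, 50))
        ]
        params = CallerParams()
        merged = merge_and_filter_junctions(recs, params)
        got = {c.id for c in enumerate_candidates(merged, params)}
        oracle = set()
        for j1 in merged:
            for j2 in merged:
                if j1 is j2 or j1.chrom != j2.chrom or j1.strand != j2.strand:
                    continue
                length = j2.start - j1.end - 1
                if params.min_gap <= length <= params.max_gap:
                    oracle.add(f"{j1.chrom}:{j1.end + 1}-{j2.start - 1}:{j1.strand}")
        assert got == oracle

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        recs = [
            JunctionRecord(
                "chr1", int(s), int(s) + int(l), "+", int(c), f"s{i % 3}"
            )
            for i, (s, l, c) in enumerate(
                zip(
                    rng.integers(1, 2000, 60),
                    rng.integers(50, 700, 60),
                    rng.integers(0, 30, 60),
                )
            )
        ]

        def ids(min_reads, min_gap, max_gap):
            p = CallerParams(min_reads, min_gap, max_gap)
            return {c.id for c in enumerate_candidates(merge_and_filter_junctions(recs, p), p)}

        assert ids(20, 12, 512) <= ids(12, 12, 512)
        assert ids(12, 12, 512) <= ids(12, 6, 600)


class TestSubtraction:
    def _candidate(self, start, end):
        return CandidateExon(
            interval=GenomicInterval("chr1", start, end, "+"),
            upstream_intron=GenomicInterval("chr1", start - 100, start - 1, "+"),
            downstream_intron=GenomicInterval("chr1", end + 1, end + 100, "+"),
            upstream_support=20,
            downstream_support=20,
        )

    def _annotation(self, exons):
        tx = TranscriptRecord(
            "T", "G", "chr1", "+", [GenomicInterval("chr1", s, e, "+") for s, e in exons]
        )
        return AnnotationModel(
            {"G": GeneRecord("G", "G", "chr1", "+", min(s for s, _ in exons), max(e for _, e in exons))},
            {"T": tx},
        )

    def test_single_base_overlap_removes(self):
        ann = self._annotation([(200, 300)])
        assert subtract_annotation([self._candidate(100, 200)], ann) == []

    def test_intron_internal_candidate_kept(self):
        ann = self._annotation([(100, 200), (800, 900)])
        kept = subtract_annotation([self._candidate(400, 500)], ann)
        assert [c.interval.start for c in kept] == [400]

    def test_opposite_strand_exon_still_removes(self):
        """Subtraction is strand-agnostic."""
        tx = TranscriptRecord(
            "T", "G", "chr1", "-", [GenomicInterval("chr1", 400, 500, "-")]
        )
        ann = AnnotationModel(
            {"G": GeneRecord("G", "G", "chr1", "-", 400, 500)}, {"T": tx}
        )
        assert subtract_annotation([self._candidate(450, 520)], ann) == []

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(29)
        exons = [
            (int(s), int(s) + int(l))
            for s, l in zip(rng.integers(1, 5000, 30), rng.integers(20, 200, 30))
        ]
        ann = self._annotation(sorted(set(exons))[:1])  # model needs sorted non-overlap
        # use an index over arbitrary (possibly overlapping) exons instead
        txs = {
            f"T{i}": TranscriptRecord(
                f"T{i}", "G", "chr1", "+", [GenomicInterval("chr1", s, e, "+")]
            )
            for i, (s, e) in enumerate(exons)
        }
        ann = AnnotationModel(ann.genes, txs)
        cands = [
            self._candidate(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(150, 5000, 40), rng.integers(12, 300, 40))
        ]
        got = {c.id for c in subtract_annotation(cands, ann)}
        oracle = {
            c.id
            for c in cands
            if not any(
                s <= c.interval.end and c.interval.start <= e for s, e in exons
            )
        }
        assert got == oracle


class TestGeneMapping:
    def test_candidate_inside_gene_span_tagged(self, toy_annotation):
        c = TestSubtraction()._candidate(300, 350)  # intron of GA
        (tagged,) = map_to_genes([c], toy_annotation)
        assert tagged.genes == ["GA"]

    def test_intergenic_candidate_untagged(self, toy_annotation):
        c = TestSubtraction()._candidate(700, 750)
        (tagged,) = map_to_genes([c], toy_annotation)
        assert tagged.genes == []

    def test_overlapping_genes_all_tagged_deterministically(self, toy_annotation):
        genes = dict(toy_annotation.genes)
        genes["GC"] = GeneRecord("GC", "GC", "chr1", "+", 250, 450)
        ann = AnnotationModel(genes, toy_annotation.transcripts)
        c = TestSubtraction()._candidate(300, 350)
        (tagged,) = map_to_genes([c], ann)
        assert tagged.genes == ["GA", "GC"]


class TestSequenceExtraction:
    def _candidate(self, start, end, strand="+"):
        return CandidateExon(
            interval=GenomicInterval("chr1", start, end, strand),
            upstream_intron=GenomicInterval("chr1", max(1, start - 50), start - 1, strand),
            downstream_intron=GenomicInterval("chr1", end + 1, end + 50, strand),
            upstream_support=20,
            downstream_support=20,
        )

    def test_flanked_length(self, random_genome):
        genomic, oriented = extract_candidate_sequence(
            self._candidate(100, 214), random_genome, flank=5
        )
        assert len(genomic) == len(oriented) == 115 + 10

    def test_minus_strand_is_reverse_complement(self, random_genome):
        genomic, oriented = extract_candidate_sequence(
            self._candidate(100, 160, "-"), random_genome, flank=5
        )
        assert oriented == reverse_complement(genomic)

    def test_flank_past_contig_start_raises(self, random_genome):
        with pytest.raises(IndexError):
            extract_candidate_sequence(self._candidate(3, 60), random_genome, flank=5)


def test_full_call_is_deterministic(tmp_path, small_dataset):
    recs = small_dataset.all_junctions()
    outs = []
    for name in ("a.bed", "b.bed"):
        cands = call_pseudoexons(recs, small_dataset.annotation)
        p = tmp_path / name
        write_candidates_bed(cands, p)
        outs.append(p.read_bytes())
    assert outs[0] == outs[1] and len(outs[0]) > 0
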