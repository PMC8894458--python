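#!/usr/bin/env python
"""Call candidate pseudoexons from the simulated cohort's junction tables:
pool read support across all samples, keep junctions with > 12 reads, pair
intron ends/starts on the same strand enclosing 12-512 bp, and drop
intervals that touch any annotated exon.

Writes results/candidates.bed and prints the per-stage record counts.
"""

from pathlib import Path

from pseudoex.io import read_annotation, read_junction_table, read_sample_sheet
from pseudoex.caller import (
    CallerParams,
    enumerate_candidates,
    map_to_genes,
    merge_and_filter_junctions,
    subtract_annotation,
    write_candidates_bed,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated_cohort"
RESULTS = ROOT / "results"


def main() -> None:
    designs = read_sample_sheet(SCRATCH / "samples.tsv")
    records = []
    for d in designs:
        records.extend(read_junction_table(d.junction_path, d.sample_id))
    annotation = read_annotation(SCRATCH / "annot.gtf")

    params = CallerParams()
    merged = merge_and_filter_junctions(records, params)
    paired = enumerate_candidates(merged, params)
    kept = subtract_annotation(paired, annotation)
    candidates = map_to_genes(kept, annotation)
    write_candidates_bed(candidates, RESULTS / "candidates.bed")

    print(f"junction rows read:              {len(records)}")
    print(f"merged junctions above threshold: {len(merged)}")
    print(f"paired candidate intervals:       {len(paired)}")
    print(f"after annotation subtraction:     {len(kept)}")
    print(f"candidates written to {RESULTS / 'candidates.bed'}")


if __name__ == "__main__":
    main()
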