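# pseudoex

Discovery and differential analysis of drug-induced **pseudoexons** —
cryptic cassette exons with adequate splice sites that are not normally
included in mature mRNA — from bulk RNA-seq splice-junction evidence.

Splice-modulating compounds such as branaplam promote inclusion of
unannotated exons carrying a non-canonical **nGA** 3'-exonic motif. A
well-studied consequence is a pseudoexon between exons 49 and 50 of the
human *HTT* gene (hg38 chr4:3213622-3213736): its 115 bp length shifts the
reading frame, introduces premature stop codons and downregulates
Huntingtin. This package implements the complete computational workflow
around that biology, for anyone analysing junction-level output of a
spliced aligner (STAR `SJ.out.tab` tables) against a GTF annotation and a
genome FASTA:

1. **Calling.** Junction read counts are pooled over all samples; junctions
   with more than 12 unique reads (8 for short-read libraries) are
   retained. Every same-strand pair of an intron end and an intron start
   enclosing 12–512 bp defines a putative exon `[J1.end+1, J2.start-1]`;
   intervals intersecting any annotated exon are discarded.
2. **Quantification.** Per-sample candidate counts, either from fragment
   intervals (≥ 1 bp overlap) or the flanking-junction fallback
   `min(upstream, downstream)`. CPM/RPKM, a 0.5-RPKM-in-≥2-samples
   expression filter, median-of-ratios size factors, and disjoint exon bins
   with 5'→3' ranks.
3. **Differential inclusion.** log2-CPM with half-count offset, a LOWESS
   mean–variance trend giving per-observation precision weights
   (sd⁻⁴ at the fitted value), per-feature weighted least squares,
   empirical-Bayes variance moderation (method of moments on log residual
   variances via digamma/trigamma identities), moderated *t* with d₀ + d
   degrees of freedom, Benjamini–Hochberg FDR. Events are called at
   adjusted p < 0.01 and log2FC > 1.
4. **Motif.** The 3-exonic + 5-intronic window at each candidate's 3' end,
   position frequency matrices, per-position information content
   (2 − Shannon entropy, bits) and exact-test enrichment of the nGA
   signature among significant events.
5. **Consequence.** Splicing a candidate into its host transcript,
   translating the spliced CDS in the original frame, reporting frameshift
   and introduced stop codons; cross-sample natural inclusion rates from a
   junction database.
6. **Washout reversibility.** Events significant under treatment are
   *persistent* if still significant after washout, else *reversible*.
7. **Simulation.** A fully self-contained generator (genome, annotation,
   negative-binomial junction/fragment counts, planted responsive sites
   with nGA motifs, ground-truth table) so the whole pipeline is testable
   without any external data.

## Worked example

The calling rule can be exercised by hand on the three junctions observed
at the *HTT* locus — the canonical intron chr4:3212710-3213957 and the two
flanking introns chr4:3212710-3213621 and chr4:3213737-3213957:

```python
from pseudoex import JunctionRecord, merge_and_filter_junctions, enumerate_candidates

junctions = [
    JunctionRecord("chr4", 3212710, 3213957, "+", 20, "s1"),
    JunctionRecord("chr4", 3212710, 3213621, "+", 20, "s1"),
    JunctionRecord("chr4", 3213737, 3213957, "+", 20, "s1"),
]
(candidate,) = enumerate_candidates(merge_and_filter_junctions(junctions))
print(candidate.id, candidate.interval.length)
```

prints

```
chr4:3213622-3213736:+ 115
```

— the pseudoexon between *HTT* exons 49 and 50; 115 mod 3 = 1, so its
inclusion is frameshifting.

## Analysis walkthrough

`analysis/` contains numbered drivers that run the full study on a
simulated cohort (3 × DMSO, 3 × branaplam, 3 × washout; 500 planted sites,
50 responsive at log2FC 3):

```sh
python analysis/01_simulate_cohort.py      # cohort + truth table
python analysis/02_call_pseudoexons.py     # junction pooling -> candidates.bed
python analysis/03_differential_inclusion.py
python analysis/04_motif_and_consequence.py
python analysis/05_washout_reversibility.py
python analysis/06_natural_inclusion_rate.py
```

A representative run prints, at the differential step,

```
branaplam vs DMSO: 376 candidates tested, 47 called (adj p < 0.01, log2FC > 1); 47 are planted responsive sites
  sensitivity 0.94, empirical FDR 0.000
```

then `nGA enrichment: odds ratio 65.8, exact p 7.54e-25` for the motif,
`washout labels: {'absent': 329, 'reversible': 46, 'persistent': 1}` for
reversibility, and a 2% natural inclusion rate for the cassette exon in a
50-sample junction database. Raw simulated files land in `scratch/`,
result tables in `results/`.

A `pseudoex` console script exposes the same stages as subcommands
(`simulate`, `call`, `quantify`, `diffsplice`, `washout`, `motif`,
`consequence`, `rate`, `run-all`).

## Layout

```
src/pseudoex/     io, caller, quantify, diffexpr, motif, consequence,
                  simulate, pipeline, cli
analysis/         numbered study drivers (thin wrappers over the library)
tests/            pytest suite with independent oracles per operation
docs/methods.md   models, parameters, numerical choices, limitations
```
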