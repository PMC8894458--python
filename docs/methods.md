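# Methods

## Coordinate conventions

All internal coordinates are 1-based inclusive. A junction's `start` and
`end` are the first and last intronic base, matching both the STAR
`SJ.out.tab` dialect and the printed *HTT* coordinates (flanking introns
chr4:3212710-3213621 / chr4:3213737-3213957 are contiguous with the exon
chr4:3213622-3213736: `upstream.end + 1 == exon.start`,
`downstream.start − 1 == exon.end`). BED output converts to 0-based
half-open at the write boundary only. Contig names are compared verbatim —
no chr-prefix aliasing.

## Pseudoexon calling

Unique-read counts are pooled per junction key (chrom, start, end, strand)
over all samples. Only pooled totals **strictly greater** than
`min_total_reads` (default 12; the 8-read variant compensates for
51-base reads, which reduce junction sensitivity) survive. Junctions with
undefined strand (STAR code 0) are parsed but excluded from pairing, which
requires a definite strand. Multi-mapping read counts are ignored: the
unique-read column is the standard support measure, and whether
multi-mappers contributed to the original totals is unknowable from the
tables, so the conservative choice is fixed here.

For every ordered pair (J1, J2) on the same contig and strand with
`J2.start > J1.end`, the enclosed interval `[J1.end+1, J2.start−1]` is a
candidate iff its **length** lies in `[min_gap, max_gap]` (12–512 bp
default). "Apart" is interpreted as this candidate-exon length
`J2.start − J1.end − 1`; the alternative reading (coordinate difference,
off by one) is not offered as an option — one definition, stated here. The
*HTT* example (length 115) is compatible with either reading and cannot
discriminate. Same-contig pairing is required in addition to same-strand
(cross-contig pairs are meaningless), and a junction never pairs with
itself. When several junction pairs imply the same interval, the
best-supported pair is kept as metadata; the candidate set is unchanged.

Annotation subtraction removes any candidate overlapping **any** exon
feature of the annotation by ≥ 1 bp, strand-agnostically — the
conservative reading of "does not intersect with any exon", and all exon
records are used, not only protein-coding transcripts. Gene assignment is
by overlap with gene transcription spans; multiple overlaps are all kept,
sorted by symbol. All outputs are sorted by (chrom, start, end, strand)
with lexicographic contig order for reproducible diffs.

## Quantification

Fragment-based counting: a fragment (read pair) counts once per feature it
overlaps by ≥ 1 bp. The overlap fraction and fragments-vs-reads choice are
not dictated by the junction tables themselves; ≥ 1 bp fragment overlap is
the simplest defensible rule and is fixed. When fragment intervals are not
available the junction fallback scores a candidate per sample as
`min(upstream, downstream)` flanking-junction reads — the number of
fragments unambiguously attributable to the included isoform. Library size
is the total fragment (or unique junction read) count of the sample, not
the column sum of the candidate matrix, because candidates are a tiny,
biased subset of the transcriptome.

CPM = count/libsize·10⁶; RPKM divides further by feature length in kb. The
expression filter keeps features with RPKM **strictly above** 0.5 in at
least 2 samples. Median-of-ratios size factors compute per-feature
geometric means over features positive in every sample and take each
sample's median ratio; the median of an even count is the mean of the two
central values. If no feature is positive everywhere the function raises,
instructing library-size normalization instead. Disjoint exon bins place
boundaries at every distinct exon start/end across a gene's transcripts;
ranks run 5'→3' in gene orientation (rank 1 is the rightmost bin of a
minus-strand gene).

## Differential inclusion model

Counts y are transformed to log2-CPM with a half-count offset,
`log2((y + 0.5)/(L + 1)·10⁶)`, finite for all non-negative counts. The
mean–variance trend is estimated by ordinary least squares per feature
against the design, then LOWESS (span 0.5, 3 robustness iterations —
standard for this trend) of the quarter-root residual variance
`sqrt(sd)` on average log2-CPM. Each observation's precision weight is the
trend prediction at its fitted value raised to the −4. Features with zero
residual variance are excluded from trend fitting but still weighted.

Per-feature weighted least squares gives coefficients β and residual
variances s² with d residual degrees of freedom. Empirical-Bayes
moderation models s² as scaled F: the prior degrees of freedom d₀ solve
`trigamma(d₀/2) = var(log s²) − trigamma(d/2)` (trigamma inverse by Newton
iteration) and the prior variance s₀² follows from the matching digamma
identity; the posterior variance is `(d₀s₀² + d·s²)/(d₀ + d)` and the
moderated t carries d₀ + d degrees of freedom. A non-finite or
non-positive moment estimate falls back to d₀ = ∞ (fully pooled variance),
logged. Setting d₀ = 0 recovers the ordinary weighted t exactly — a tested
identity. p-values are two-sided; BH step-up adjustment restores input
order. Significance uses strict inequalities: adjusted p < α (default
0.01) and log2FC > 1 (or |log2FC| for two-directional calls). The contrast
is always treatment − reference.

Counts, not RPKM, enter the linear model: precision weights are defined on
the count scale, and normalization is carried by the library-size term of
the log-CPM transform.

Washout classification is a pure function of the two significance flags:
significant before and after washout → persistent; before only →
reversible; not significant before → absent. The washout contrast
(washout-vs-control here) is a caller choice, not fixed by the model. The
per-exon fold-change profile normalizes by median-of-ratios size factors
and reports `log2((mean treated + 0.5)/(mean control + 0.5))` per bin plus
the median across bins.

## Motif

The 3+5 window is the last 3 exonic and first 5 intronic bases at the
candidate's **3' end** in gene orientation (reverse complement on the
minus strand). The alternative phrasing that places the window at the 5'
end is treated as a typo: the motif of interest (nGA) is 3'-exonic by
definition. Windows containing non-ACGT bases are excluded from matrices
rather than fractionally counted. Information content per position is
2 − Shannon entropy in bits with no small-sample correction. nGA
constrains only positions 2–3 of the exonic triplet; the first base is
free. Enrichment uses Fisher's exact test (hypergeometric enumeration;
candidate sets number in the tens, where asymptotic χ² would be
unreliable) with a Haldane–Anscombe 0.5 correction for zero cells of the
odds ratio only.

## Consequence

A candidate splices into a transcript only strictly inside an intron (at
least one intronic base on each side). The annotated CDS excludes the
terminal stop codon (Ensembl convention), so an unmodified transcript
translates without stops. Translation uses the standard nuclear code;
selenocysteine recoding is ignored. A stop codon is attributed to the
pseudoexon when its **first base** lies inside the pseudoexon interval —
codons may straddle splice junctions. Insertions upstream of the CDS are
reported as non-coding, not errors.

The natural inclusion rate over a cross-sample junction database is
`100·|S_up ∩ S_dn| / |S_excl ∪ (S_up ∩ S_dn)|` with S the
supporting-sample sets of the two inclusion junctions and the exclusion
(canonical) junction. Including the inclusion samples in the denominator
bounds the rate to [0, 100] by construction; a database may define the
denominator differently, so the computed rate is this definition's, not a
universal one.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
two-arm (optionally three-arm washout) design with 3 replicates per
condition; 500 candidate sites planted strictly inside introns of
multi-exon genes, 50 responsive with true inclusion log2FC 3 over a
baseline mean of 2 reads per inclusion junction; negative-binomial counts
with variance μ + φμ², φ = 0.1 (typical bulk RNA-seq dispersion);
per-sample depth factors uniform in [0.8, 1.2]; canonical junction means
uniform in [30, 80] per gene. Responsive sites carry an nGA terminal
triplet with probability 0.9, background sites 0.25; donor context is an
invariant GT followed by consensus-weighted A-rich bases. The persistent
fraction after washout defaults to 2/138, the scale observed when nearly
all treatment-induced events revert. Coding sequences are rewritten with
stop-free codons so wild-type translation is clean.

Not emulated: GC/repeat structure (genome background is i.i.d. uniform
ACGT), positional read biases, overdispersion heterogeneity across genes,
alignment artifacts, and incomplete annotation beyond the planted sites.
Passing recovery tests therefore demonstrates the statistical machinery
under the model's own assumptions, not robustness to real-data artifacts.
All randomness flows from a single `numpy` generator seeded by the config;
identical configs give byte-identical output files.

## Problem sizes and test design

The simulated cohorts used by the test suite and analysis drivers use 150
genes (≈ 675 introns) and 500 planted sites, the default study scale;
unit-test fixtures are smaller (tens of sites). Recovery criteria pool
true/false positives over five seeds, since a single 3-vs-3 draw at
baseline mean 2 is noisy: single-seed sensitivity ranges roughly 0.7–1.0
while the pooled value is stable. During development the moderated-t path
was cross-checked against an independent reference implementation of the
same weighted moderated linear model on one simulated matrix (t-statistic
correlation > 0.99); the committed tests rely on self-contained
step-by-step formula oracles instead.

## Known limitations

- The junction fallback understates coverage for candidates supported by
  non-junction reads; fragment-interval import is preferred when BAMs are
  available.
- The caller does not score splice-site strength; any same-strand
  end/start pair in range is a candidate, so annotation completeness
  drives specificity.
- Inclusion-rate denominators depend on the external database's sample
  universe; only the relative definition above is implemented.
- The moderated model assumes a common mean–variance trend; strong
  subpopulations of features (e.g., mixed bulk/single-cell) would violate
  it.
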