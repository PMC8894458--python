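"""Self-contained synthetic datasets for exercising the whole pipeline.

The generator emulates the statistical structure the analysis assumes: a
multi-gene genome of i.i.d. uniform ACGT background; multi-exon transcripts
with stop-free coding sequences; unannotated candidate exons planted
strictly inside introns with AG/GT splice context and a configurable
terminal nGA motif; and per-sample splice-junction tables whose counts are
negative binomial (variance = mu + phi*mu^2). Canonical junctions carry
gene-level means; the two inclusion junctions of a planted site carry the
baseline mean in control samples and baseline * 2^effect in treated samples
for responsive sites. An optional washout arm returns reversible sites to
baseline and keeps the small persistent fraction elevated.

The default configuration is a 3-vs-3 two-condition design with 500
candidate sites of which 50 are responsive at a true effect of log2FC = 3
over a baseline inclusion mean of 2 reads per junction.

Everything is deterministic under the config seed; no global random state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pseudoex.io import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    InMemoryGenome,
    JunctionRecord,
    SampleDesign,
    TranscriptRecord,
    reverse_complement,
    write_junction_table,
    write_sample_sheet,
)

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (120, 200)
    intron_length: tuple[int, int] = (700, 1200)
    candidate_length: tuple[int, int] = (60, 180)
    n_candidate_sites: int = 500
    n_responsive: int = 50
    inclusion_log2fc: float = 3.0
    baseline_inclusion_reads: float = 2.0
    nb_dispersion: float = 0.1
    replicates: int = 3
    conditions: tuple[str, ...] = ("DMSO", "branaplam")
    canonical_mean_range: tuple[float, float] = (30.0, 80.0)
    depth_factor_range: tuple[float, float] = (0.8, 1.2)
    nga_fraction_responsive: float = 0.9
    nga_fraction_background: float = 0.25
    persistent_fraction: float = 2.0 / 138.0
    genes_per_contig: int = 25
    intergenic_spacer: int = 400

    def __post_init__(self) -> None:
        if self.n_responsive > self.n_candidate_sites:
            raise ValueError("n_responsive exceeds n_candidate_sites")
        for frac in (
            self.nga_fraction_responsive,
            self.nga_fraction_background,
            self.persistent_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(
            self.n_genes,
            self.n_candidate_sites,
            self.replicates,
        ) < 1:
            raise ValueError("counts must be positive")
        if not np.isfinite(self.inclusion_log2fc):
            raise ValueError("effect size must be finite")
        min_intron = self.intron_length[0]
        if self.candidate_length[1] + 20 > min_intron:
            raise ValueError("introns too short for planted candidate sites")


@dataclass
class PlantedSite:
    site_id: str
    gene_id: str
    interval: GenomicInterval  # the planted exon, genomic coordinates
    strand: str
    responsive: bool
    persistent: bool
    true_log2fc: float
    motif_window: str  # oriented 8-mer: 3 exonic + 5 intronic
    upstream_intron: GenomicInterval  # inclusion junction, genomic-left
    downstream_intron: GenomicInterval  # inclusion junction, genomic-right
    exclusion_intron: GenomicInterval  # the canonical intron spanning the site


@dataclass
class TruthTable:
    sites: list[PlantedSite]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self.sites],
                "gene_id": [s.gene_id for s in self.sites],
                "chrom": [s.interval.chrom for s in self.sites],
                "start": [s.interval.start for s in self.sites],
                "end": [s.interval.end for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "responsive": [s.responsive for s in self.sites],
                "persistent": [s.persistent for s in self.sites],
                "true_log2fc": [s.true_log2fc for s in self.sites],
                "motif_window": [s.motif_window for s in self.sites],
            }
        )

    def by_id(self) -> dict[str, PlantedSite]:
        return {s.site_id: s for s in self.sites}


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: InMemoryGenome
    annotation: AnnotationModel
    truth: TruthTable
    designs: list[SampleDesign]
    junctions: dict[str, list[JunctionRecord]]  # sample_id -> records
    fragments: dict[str, list[GenomicInterval]]
    gene_means: dict[str, float]

    def all_junctions(self) -> list[JunctionRecord]:
        return [r for recs in self.junctions.values() for r in recs]


def _write_codons(
    seq: list[str], positions: list[int], strand: str, rng: np.random.Generator
) -> None:
    """Overwrite CDS positions (translation order) with stop-free codons."""
    n_codons = len(positions) // 3
    codons = rng.choice(_NON_STOP_CODONS, size=n_codons)
    bases = "".join(codons)
    for p, b in zip(positions, bases):
        seq[p - 1] = b if strand != "-" else reverse_complement(b)


def simulate_genome_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[InMemoryGenome, AnnotationModel, TruthTable, dict[str, float]]:
    """Genome, annotation and planted-site truth, deterministic under seed."""
    rng = rng or np.random.default_rng(config.seed)
    contig_seqs: dict[str, list[str]] = {}
    genes: dict[str, GeneRecord] = {}
    transcripts: dict[str, TranscriptRecord] = {}
    gene_means: dict[str, float] = {}
    introns: list[tuple[str, int, GenomicInterval, GenomicInterval, GenomicInterval]] = []
    # (gene_id, intron_idx, left_exon, right_exon, intron)

    cursor: dict[str, int] = {}
    for gi in range(config.n_genes):
        contig = f"chr{gi // config.genes_per_contig + 1}"
        if contig not in contig_seqs:
            contig_seqs[contig] = []
            cursor[contig] = 0
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_ex
        )
        in_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=n_ex - 1
        )
        gene_len = int(ex_lens.sum() + in_lens.sum())
        spacer = config.intergenic_spacer
        start = cursor[contig] + spacer + 1
        seq_chunk = rng.choice(list("ACGT"), size=gene_len + spacer)
        contig_seqs[contig].extend(seq_chunk.tolist())
        cursor[contig] += gene_len + spacer

        exons = []
        pos = start
        for k in range(n_ex):
            exons.append(GenomicInterval(contig, pos, pos + int(ex_lens[k]) - 1, strand))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        gene_end = exons[-1].end
        genes[gene_id] = GeneRecord(gene_id, gene_id, contig, strand, start, gene_end)
        tx_id = f"{gene_id}.t1"
        transcripts[tx_id] = TranscriptRecord(tx_id, gene_id, contig, strand, exons)
        gene_means[gene_id] = float(
            rng.uniform(config.canonical_mean_range[0], config.canonical_mean_range[1])
        )
        for k in range(n_ex - 1):
            intron = GenomicInterval(contig, exons[k].end + 1, exons[k + 1].start - 1, strand)
            introns.append((gene_id, k, exons[k], exons[k + 1], intron))

    # flatten contig sequences into mutable base lists
    seqs = {c: list("".join(s)) for c, s in contig_seqs.items()}

    # assign CDS spans and rewrite with stop-free codons
    for tx in transcripts.values():
        exons = tx.exons
        cds_start = exons[0].start + 9
        cds_end = exons[-1].end - 9
        positions = [
            p
            for ex in exons
            for p in range(max(ex.start, cds_start), min(ex.end, cds_end) + 1)
        ]
        # trim to a codon multiple from the 3' end in transcript orientation
        excess = len(positions) % 3
        if tx.strand == "-":
            positions = positions[::-1]
        if excess:
            positions = positions[:-excess]
        tx.cds_start = min(positions)
        tx.cds_end = max(positions)
        _write_codons(seqs[tx.chrom], positions, tx.strand, rng)

    # choose introns to host planted sites
    if config.n_candidate_sites > len(introns):
        raise ValueError(
            f"config plants {config.n_candidate_sites} sites but only "
            f"{len(introns)} introns exist; increase n_genes"
        )
    host_idx = rng.choice(len(introns), size=config.n_candidate_sites, replace=False)
    responsive_mask = np.zeros(config.n_candidate_sites, dtype=bool)
    responsive_mask[: config.n_responsive] = True
    persistent_mask = np.zeros(config.n_candidate_sites, dtype=bool)
    persistent_mask[: config.n_responsive] = (
        rng.random(config.n_responsive) < config.persistent_fraction
    )

    sites: list[PlantedSite] = []
    for si, (idx, resp, pers) in enumerate(
        zip(host_idx, responsive_mask, persistent_mask)
    ):
        gene_id, _k, left_ex, right_ex, intron = introns[idx]
        strand = genes[gene_id].strand
        contig = intron.chrom
        ex_len = int(
            rng.integers(config.candidate_length[0], config.candidate_length[1] + 1)
        )
        # leave >= 8 intronic bases on each side so flanking junctions exist
        lo = intron.start + 8
        hi = intron.end - 8 - ex_len + 1
        site_start = int(rng.integers(lo, hi + 1))
        site = GenomicInterval(contig, site_start, site_start + ex_len - 1, strand)

        nga_frac = (
            config.nga_fraction_responsive if resp else config.nga_fraction_background
        )
        if rng.random() < nga_frac:
            triplet = rng.choice(list("ACGT")) + "GA"
        else:
            # any triplet that is not nGA
            while True:
                triplet = "".join(rng.choice(list("ACGT"), size=3))
                if not (triplet[1] == "G" and triplet[2] == "A"):
                    break
        # donor: invariant GT, then consensus-weighted A-rich positions
        donor_tail = "".join(
            rng.choice(list("ACGT"), p=probs)
            for probs in ([0.55, 0.05, 0.3, 0.1], [0.6, 0.1, 0.2, 0.1], [0.2, 0.1, 0.5, 0.2])
        )
        window = triplet + "GT" + donor_tail
        _plant_site_context(seqs[contig], site, strand, window, rng)

        sites.append(
            PlantedSite(
                site_id=f"{contig}:{site.start}-{site.end}:{strand}",
                gene_id=gene_id,
                interval=site,
                strand=strand,
                responsive=bool(resp),
                persistent=bool(pers),
                true_log2fc=config.inclusion_log2fc if resp else 0.0,
                motif_window=window,
                upstream_intron=GenomicInterval(
                    contig, left_ex.end + 1, site.start - 1, strand
                ),
                downstream_intron=GenomicInterval(
                    contig, site.end + 1, right_ex.start - 1, strand
                ),
                exclusion_intron=intron,
            )
        )

    genome = InMemoryGenome({c: "".join(s) for c, s in seqs.items()})
    annotation = AnnotationModel(genes, transcripts)
    return genome, annotation, TruthTable(sites), gene_means


def _plant_site_context(
    seq: list[str],
    site: GenomicInterval,
    strand: str,
    window: str,
    rng: np.random.Generator,
) -> None:
    """Write splice context and terminal motif around a planted exon.

    In gene orientation: the upstream intron ends with AG just before the
    exon, the exon's last 3 bases are the motif triplet, and the downstream
    intron starts with the window's 5 intronic bases (GT donor).
    """

    def put(pos: int, bases: str) -> None:
        # oriented write: for '-' strand, bases run 3'->5' genomically
        if strand == "-":
            bases = reverse_complement(bases)
            pos = pos - len(bases) + 1
        for i, b in enumerate(bases):
            seq[pos - 1 + i] = b

    if strand == "-":
        # acceptor AG upstream in transcript orientation = genomic right
        put(site.end + 2, "AG")
        # exonic triplet at transcript 3' end = genomic start..start+2
        put(site.start + 2, window[:3])
        put(site.start - 1, window[3:])
    else:
        put(site.start - 2, "AG")
        put(site.end - 2, window[:3])
        put(site.end + 1, window[3:])


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with variance mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def make_designs(config: SimulationConfig) -> list[SampleDesign]:
    return [
        SampleDesign(sample_id=f"{cond}_{r + 1}", condition=cond, replicate=r + 1)
        for cond in config.conditions
        for r in range(config.replicates)
    ]


def simulate_junction_counts(
    truth: TruthTable,
    annotation: AnnotationModel,
    gene_means: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[SampleDesign], dict[str, list[JunctionRecord]]]:
    """Per-sample junction tables with NB counts.

    Canonical junctions (all consecutive exon pairs of every transcript)
    get gene-level means; inclusion junctions of planted sites get the
    baseline mean, raised by 2^effect in treated samples for responsive
    sites (and in washout samples for persistent sites only).
    """
    designs = make_designs(config)
    control = config.conditions[0]
    treated = config.conditions[1] if len(config.conditions) > 1 else control
    phi = config.nb_dispersion
    out: dict[str, list[JunctionRecord]] = {}
    finished: list[SampleDesign] = []
    for d in designs:
        depth = float(rng.uniform(*config.depth_factor_range))
        recs: list[JunctionRecord] = []
        for tx in annotation.transcripts.values():
            mu = gene_means[tx.gene_id] * depth
            for a, b in zip(tx.exons, tx.exons[1:]):
                cnt = int(_nb_draw(rng, mu, phi))
                recs.append(
                    JunctionRecord(
                        tx.chrom, a.end + 1, b.start - 1, tx.strand, cnt, d.sample_id
                    )
                )
        for s in truth.sites:
            if d.condition == control:
                elevated = False
            elif d.condition == treated:
                elevated = s.responsive
            else:  # washout arm
                elevated = s.responsive and s.persistent
            mu = config.baseline_inclusion_reads * depth
            if elevated:
                mu *= 2.0**s.true_log2fc
            for intron in (s.upstream_intron, s.downstream_intron):
                cnt = int(_nb_draw(rng, mu, phi))
                recs.append(
                    JunctionRecord(
                        intron.chrom,
                        intron.start,
                        intron.end,
                        s.strand,
                        cnt,
                        d.sample_id,
                    )
                )
        total = sum(r.unique_reads for r in recs)
        out[d.sample_id] = recs
        finished.append(
            SampleDesign(d.sample_id, d.condition, d.replicate, library_size=total)
        )
    return finished, out


def simulate_fragments(
    truth: TruthTable,
    junctions: dict[str, list[JunctionRecord]],
    config: SimulationConfig,
    rng: np.random.Generator,
    fragment_length: int = 200,
) -> dict[str, list[GenomicInterval]]:
    """Fragment intervals over planted sites, coupled to inclusion support.

    The number of fragments over a site in a sample is the rounded mean of
    its two inclusion-junction counts in that sample; fragments are placed
    uniformly so that each overlaps the site by >= 1 bp.
    """
    idx: dict[str, dict[tuple[str, int, int, str], int]] = {}
    for sid, recs in junctions.items():
        d = {}
        for r in recs:
            d[(r.chrom, r.start, r.end, r.strand)] = r.unique_reads
        idx[sid] = d
    out: dict[str, list[GenomicInterval]] = {}
    for sid, jmap in idx.items():
        frags: list[GenomicInterval] = []
        for s in truth.sites:
            up = s.upstream_intron
            dn = s.downstream_intron
            c1 = jmap.get((up.chrom, up.start, up.end, s.strand), 0)
            c2 = jmap.get((dn.chrom, dn.start, dn.end, s.strand), 0)
            n = int(round((c1 + c2) / 2.0))
            for _ in range(n):
                lo = s.interval.start - fragment_length + 1
                start = int(rng.integers(lo, s.interval.end + 1))
                frags.append(
                    GenomicInterval(
                        s.interval.chrom, max(1, start), start + fragment_length - 1, s.strand
                    )
                )
        out[sid] = frags
    return out


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate the full bundle; optionally write all files under ``outdir``.

    Files written: genome.fa, annot.gtf, SJ_<sample>.tab per sample,
    fragments_<sample>.bed per sample, samples.tsv, truth.tsv.
    """
    rng = np.random.default_rng(config.seed)
    genome, annotation, truth, gene_means = simulate_genome_annotation(config, rng)
    designs, junctions = simulate_junction_counts(
        truth, annotation, gene_means, config, rng
    )
    fragments = simulate_fragments(truth, junctions, config, rng)
    ds = SimulatedDataset(
        config, genome, annotation, truth, designs, junctions, fragments, gene_means
    )
    if outdir is not None:
        write_dataset(ds, Path(outdir))
    return ds


def write_dataset(ds: SimulatedDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom in ds.genome.contigs():
            fh.write(f">{chrom}\n")
            seq = ds.genome.fetch(chrom, 1, ds.genome.contig_length(chrom))
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    write_gtf(ds.annotation, outdir / "annot.gtf")
    designs = []
    for d in ds.designs:
        path = outdir / f"SJ_{d.sample_id}.tab"
        write_junction_table(ds.junctions[d.sample_id], path)
        designs.append(
            SampleDesign(
                d.sample_id, d.condition, d.replicate, path.name, d.library_size
            )
        )
        with open(outdir / f"fragments_{d.sample_id}.bed", "w") as fh:
            for fr in ds.fragments[d.sample_id]:
                fh.write(f"{fr.chrom}\t{fr.start - 1}\t{fr.end}\t.\t0\t{fr.strand}\n")
    write_sample_sheet(designs, outdir / "samples.tsv")
    ds.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def write_gtf(annotation: AnnotationModel, path: Path) -> None:
    with open(path, "w") as fh:
        for gid, g in annotation.genes.items():
            attrs = f'gene_id "{gid}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx in annotation.transcripts.values():
                if tx.gene_id != gid:
                    continue
                tattrs = f'gene_id "{gid}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\tsim\ttranscript\t{tx.exons[0].start}\t"
                    f"{tx.exons[-1].end}\t.\t{tx.strand}\t.\t{tattrs}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tsim\texon\t{ex.start}\t{ex.end}\t.\t"
                        f"{tx.strand}\t.\t{tattrs}\n"
                    )
                if tx.cds_start is not None:
                    for ex in tx.exons:
                        a = max(ex.start, tx.cds_start)
                        b = min(ex.end, tx.cds_end)
                        if a <= b:
                            fh.write(
                                f"{tx.chrom}\tsim\tCDS\t{a}\t{b}\t.\t{tx.strand}\t0"
                                f"\t{tattrs}\n"
                            )
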