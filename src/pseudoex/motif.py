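"""Splice-donor motif characterization at the candidate 3' end.

The window is an 8-mer in XXX|YYYYY format: the last three exonic bases of
the candidate followed by the first five intronic bases downstream, taken
in gene orientation (reverse-complemented for minus-strand candidates).
Position frequency matrices and per-position information content
(2 - Shannon entropy, bits, no small-sample correction) summarize window
sets; enrichment of the nGA signature — exonic positions 2-3 being G then
A, any first base — is scored with an exact two-sided 2x2 test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pseudoex.io import GenomeAccessor, reverse_complement
from pseudoex.caller import CandidateExon

ALPHABET = "ACGT"
N_EXONIC = 3
N_INTRONIC = 5
WINDOW_LEN = N_EXONIC + N_INTRONIC


@dataclass
class MotifMatrix:
    """Per-position base counts over a set of 8-mer windows."""

    counts: pd.DataFrame  # rows A,C,G,T; columns positions 1..8
    n_sequences: int

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    @property
    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: 2 - Shannon entropy of base frequencies."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=0)
        return 2.0 - ent


def three_five_window(candidate: CandidateExon, genome: GenomeAccessor) -> str:
    """3 exonic + 5 intronic bases at the candidate's 3' end, strand-oriented.

    Plus strand: genome[end-2..end] + genome[end+1..end+5]. Minus strand:
    reverse complement of genome[start-5..start+2]. Raises ``IndexError``
    when the window crosses a contig boundary, ``ValueError`` if the
    candidate is shorter than 3 bp.
    """
    iv = candidate.interval
    if iv.length < N_EXONIC:
        raise ValueError(f"candidate {candidate.id} shorter than {N_EXONIC} bp")
    if iv.strand == "-":
        return reverse_complement(
            genome.fetch(iv.chrom, iv.start - N_INTRONIC, iv.start + N_EXONIC - 1)
        )
    return genome.fetch(iv.chrom, iv.end - N_EXONIC + 1, iv.end + N_INTRONIC)


def valid_window(window: str) -> bool:
    return len(window) == WINDOW_LEN and all(b in ALPHABET for b in window)


def build_motif(windows: Sequence[str]) -> MotifMatrix:
    """Tally a position frequency matrix; windows containing non-ACGT bases
    are excluded rather than fractionally counted."""
    usable = [w.upper() for w in windows if valid_window(w.upper())]
    if not usable:
        raise ValueError("no valid windows")
    counts = np.zeros((4, WINDOW_LEN), dtype=int)
    for w in usable:
        for pos, base in enumerate(w):
            counts[ALPHABET.index(base), pos] += 1
    df = pd.DataFrame(
        counts, index=list(ALPHABET), columns=range(1, WINDOW_LEN + 1)
    )
    return MotifMatrix(df, len(usable))


def is_nga(window: str) -> bool:
    """nGA: exonic positions 2-3 (of the XXX triplet) are G then A."""
    w = window.upper()
    return len(w) >= N_EXONIC and w[1] == "G" and w[2] == "A"


def nga_enrichment(
    foreground: Sequence[str], background: Sequence[str]
) -> tuple[float, float]:
    """(odds ratio, two-sided exact p) for nGA in foreground vs background.

    The odds ratio uses the Haldane-Anscombe 0.5 correction when any cell
    of the 2x2 table is zero; the p-value is Fisher's exact test
    (hypergeometric enumeration).
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    a = sum(is_nga(w) for w in foreground)
    b = len(foreground) - a
    c = sum(is_nga(w) for w in background)
    d = len(background) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def motif_matrix_to_tsv(matrix: MotifMatrix, path) -> None:
    out = matrix.counts.copy()
    out.loc["IC_bits"] = matrix.information_content
    out.to_csv(path, sep="\t", index_label="base")
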