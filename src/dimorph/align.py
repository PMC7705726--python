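"""Global pairwise nucleotide identity between two mRNA sequences.

Used to quantify cross-species conservation of a transcript (e.g. the
chicken versus quail HEMGN mRNAs).  Scoring follows the EMBOSS ``needle``
defaults for DNA — match +5, mismatch −4, gap open 10, gap extend 0.5 —
and identity is the fraction of alignment columns (gaps included) where
the two letters agree, reported as a percentage.
"""

from __future__ import annotations

from pathlib import Path

from Bio import Align, SeqIO


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the best global alignment of two sequences."""
    aligner = make_aligner()
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


def fasta_identity(path_a: str | Path, path_b: str | Path) -> float:
    """Percent identity between the first records of two FASTA files."""
    rec_a = next(SeqIO.parse(str(path_a), "fasta"))
    rec_b = next(SeqIO.parse(str(path_b), "fasta"))
    return global_identity(str(rec_a.seq), str(rec_b.seq))
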