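"""Pre-analysis read quality filtering.

Reads are screened with four thresholds before any mapping or selection
analysis: minimum length 60 nt, minimum arithmetic-mean Phred quality 30,
at most 4 N bases, and a minimum low-complexity (entropy) score of 70 on a
0-100 scale.  The entropy score is the Shannon entropy of overlapping
trinucleotide frequencies normalised by the maximum attainable for the
read length, so a homopolymer scores 0 and a maximally diverse read scores
100.  Rejected reads carry the first failing rule in a fixed order
(length, quality, N count, complexity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .synth import Read, ReadSet

__all__ = ["QCParams", "entropy_score", "filter_reads", "read_fastq", "write_report"]


@dataclass
class QCParams:
    min_length_nt: int = 60
    min_mean_quality: float = 30.0
    max_n_count: int = 4
    min_entropy_score: float = 70.0

    def validate(self) -> None:
        if min(self.min_length_nt, self.min_mean_quality, self.max_n_count,
               self.min_entropy_score) < 0:
            raise ValueError("QC thresholds must be non-negative")


def entropy_score(sequence: str) -> float:
    """Complexity score in [0, 100] from overlapping 3-mer frequencies."""
    seq = sequence.upper()
    n_kmers = len(seq) - 2
    if n_kmers < 1:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(n_kmers):
        kmer = seq[i : i + 3]
        counts[kmer] = counts.get(kmer, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_kmers
        h -= p * math.log2(p)
    h_max = math.log2(min(64, n_kmers))
    if h_max <= 0.0:
        return 0.0
    return 100.0 * h / h_max


def _mean_quality(quality: str) -> float:
    if not quality:
        return 0.0
    total = 0
    for ch in quality:
        q = ord(ch) - 33
        if q < 0:
            raise ValueError(f"quality character below Phred+33 range: {ch!r}")
        total += q
    return total / len(quality)


def _first_failure(read: Read, params: QCParams) -> str | None:
    if len(read.sequence) < params.min_length_nt:
        return "length"
    if _mean_quality(read.quality) < params.min_mean_quality:
        return "quality"
    if read.sequence.upper().count("N") > params.max_n_count:
        return "N-count"
    if entropy_score(read.sequence) < params.min_entropy_score:
        return "complexity"
    return None


def filter_reads(
    reads: ReadSet, params: QCParams | None = None
) -> tuple[ReadSet, list[tuple[str, str]]]:
    """Partition a read set into kept reads and (read_id, reason) rejects."""
    params = params or QCParams()
    params.validate()
    kept: list[Read] = []
    rejected: list[tuple[str, str]] = []
    for read in reads.reads:
        if len(read.quality) != len(read.sequence):
            raise ValueError(f"malformed record {read.read_id}: quality length mismatch")
        reason = _first_failure(read, params)
        if reason is None:
            kept.append(read)
        else:
            rejected.append((read.read_id, reason))
    kept_set = ReadSet(
        reads=kept,
        read_length_range=reads.read_length_range,
        mean_depth=reads.mean_depth,
    )
    return kept_set, rejected


def read_fastq(path: str | Path) -> ReadSet:
    """Load a Sanger FASTQ file into a ReadSet (origin fields unknown)."""
    from Bio import SeqIO

    reads = []
    min_len = None
    max_len = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq)
        quality = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(
            Read(
                read_id=rec.id,
                sequence=seq,
                quality=quality,
                genome="",
                haplotype=-1,
                start=-1,
                strand=".",
            )
        )
        min_len = len(seq) if min_len is None else min(min_len, len(seq))
        max_len = max(max_len, len(seq))
    return ReadSet(reads=reads, read_length_range=(min_len or 0, max_len), mean_depth=0.0)


def write_report(rejected: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in rejected:
            fh.write(f"{read_id}\t{reason}\n")
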