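"""Read-to-reference alignments, the 80/80 rule, and pileups.

Alignments can be ingested from SAM (identity requires an MD tag or =/X
CIGAR operations) or produced by an internal desk-scale mapper (k-mer
seeding plus banded semi-global extension via edlib).  The study's mapping
acceptance rule — at least 80% identity over aligned columns and at least
80% of the read aligned — is applied by :func:`filter_alignments` with
inclusive thresholds.

Conventions: coordinates are 0-based half-open internally; identity is
matches/(matches+mismatches) over aligned columns (clips and gaps
excluded); read coverage is aligned read bases over the full read length
including clips.  Insertions relative to the reference contribute nothing
to pileups and deletions contribute no base: the downstream selection
analysis is substitution-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synth import ReadSet, reverse_complement

__all__ = [
    "Alignment",
    "Pileup",
    "read_sam",
    "write_sam",
    "ReferenceIndex",
    "map_reads_simple",
    "filter_alignments",
    "build_pileup",
]

_BASE_TO_IDX = bytes.maketrans(b"ACGTacgt", bytes([0, 1, 2, 3, 0, 1, 2, 3]))
_IDX_OK = frozenset(b"ACGTacgt")


@dataclass
class Alignment:
    """One read-to-reference alignment (gapped, strand-resolved).

    ``read_seq`` is the aligned read sequence in forward-reference
    orientation (as in a SAM record); ``ref_positions``/``read_positions``
    are the matched (non-gap) columns used for pileup construction.
    """

    read_id: str
    reference_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    read_coverage: float
    read_seq: str
    ref_positions: np.ndarray
    read_positions: np.ndarray

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.ref_positions.tolist(), self.read_positions.tolist()))


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> tuple[list[Alignment], int]:
    """Parse a SAM file into alignments; returns (alignments, n_unmapped).

    Identity needs =/X CIGAR operations or an MD tag; records providing
    neither raise an error instructing the caller to supply one.
    """
    import pysam

    alignments: list[Alignment] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            cigar = rec.cigartuples or []
            has_eqx = any(op in (7, 8) for op, _ in cigar)
            if has_eqx:
                matches = sum(n for op, n in cigar if op == 7)
                mismatches = sum(n for op, n in cigar if op == 8)
            elif rec.has_tag("MD"):
                ref_seq = rec.get_reference_sequence()
                matches = mismatches = 0
                qseq = rec.query_sequence
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                    if qseq[qpos].upper() == ref_seq[rpos - rec.reference_start].upper():
                        matches += 1
                    else:
                        mismatches += 1
            else:
                raise ValueError(
                    f"record {rec.query_name}: identity not computable; provide an "
                    "MD tag or =/X CIGAR operations"
                )
            aligned_cols = matches + mismatches
            identity = matches / aligned_cols if aligned_cols else 0.0
            full_len = rec.infer_read_length() or rec.query_length
            coverage = rec.query_alignment_length / full_len if full_len else 0.0

            pairs = rec.get_aligned_pairs(matches_only=True)
            ref_positions = np.fromiter((r for _, r in pairs), dtype=np.int64)
            read_positions = np.fromiter((q for q, _ in pairs), dtype=np.int64)
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    reference_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    identity=identity,
                    read_coverage=coverage,
                    read_seq=rec.query_sequence or "",
                    ref_positions=ref_positions,
                    read_positions=read_positions,
                )
            )
    return alignments, n_unmapped


# ---------------------------------------------------------------------------
# internal simple mapper
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact k-mer location index over a set of reference sequences."""

    def __init__(self, references: Mapping[str, str], k: int = 15):
        self.k = k
        self.references = dict(references)
        self.names = sorted(self.references)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ni, name in enumerate(self.names):
            seq = self.references[name].upper()
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                self.index.setdefault(kmer, []).append((ni, pos))


def _cigar_to_pairs(
    cigar: str, ref_start: int
) -> tuple[np.ndarray, np.ndarray, int, int, int]:
    """Expand an edlib extended CIGAR into matched-column coordinate arrays."""
    ref_positions: list[int] = []
    read_positions: list[int] = []
    matches = mismatches = 0
    rpos = ref_start
    qpos = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            ref_positions.extend(range(rpos, rpos + n))
            read_positions.extend(range(qpos, qpos + n))
            if ch == "=":
                matches += n
            else:
                mismatches += n
            rpos += n
            qpos += n
        elif ch == "I":  # insertion in read relative to reference
            qpos += n
        elif ch == "D":
            rpos += n
        else:  # pragma: no cover - edlib emits only =XID
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return (
        np.asarray(ref_positions, dtype=np.int64),
        np.asarray(read_positions, dtype=np.int64),
        matches,
        mismatches,
        rpos,
    )


def _seed_votes(
    seq: str, index: ReferenceIndex, n_seeds: int = 8
) -> dict[tuple[int, int], int]:
    k = index.k
    span = len(seq) - k
    if span < 0:
        return {}
    step = max(1, span // max(1, n_seeds - 1)) if span else 1
    votes: dict[tuple[int, int], int] = {}
    for off in range(0, span + 1, step):
        for ni, pos in index.index.get(seq[off : off + k], ()):
            key = (ni, pos - off)
            votes[key] = votes.get(key, 0) + 1
    return votes


def map_reads_simple(
    reads: ReadSet,
    references: Mapping[str, str] | ReferenceIndex,
    k: int = 15,
    max_divergence: float = 0.25,
) -> list[Alignment]:
    """Map each read to its best-scoring location (or drop it).

    Seeding: up to 8 evenly spaced exact k-mers vote for (reference,
    diagonal) in both orientations; the top diagonal per orientation is
    extended with an infix (semi-global) edlib alignment of the read
    against a padded reference window.  The lower edit distance wins;
    ties break to the forward strand, then the lowest (reference_id,
    position).  Reads with no seed hit or alignments beyond
    ``max_divergence`` edits per read base are unmapped and simply absent.
    """
    import edlib

    if isinstance(references, ReferenceIndex):
        index = references
    else:
        if not references:
            raise ValueError("references must be non-empty")
        index = ReferenceIndex(references, k=k)

    alignments: list[Alignment] = []
    for read in reads.reads:
        candidates: list[tuple[int, int, int, str, str]] = []
        for strand in "+-":
            seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
            votes = _seed_votes(seq.upper(), index)
            if not votes:
                continue
            best = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            (ni, diag), _ = best
            candidates.append((ni, diag, 0, strand, seq))
        best_result = None
        for ni, diag, _, strand, seq in candidates:
            ref_name = index.names[ni]
            ref_seq = index.references[ref_name]
            pad = max(8, int(0.15 * len(seq)))
            w_start = max(0, diag - pad)
            w_end = min(len(ref_seq), diag + len(seq) + pad)
            window = ref_seq[w_start:w_end].upper()
            max_k = int(max_divergence * len(seq))
            res = edlib.align(seq.upper(), window, mode="HW", task="path", k=max_k)
            if res["editDistance"] < 0:
                continue
            loc = res["locations"][0]
            key = (res["editDistance"], 0 if strand == "+" else 1, ni, w_start + loc[0])
            if best_result is None or key < best_result[0]:
                best_result = (key, ni, strand, seq, res, w_start)
        if best_result is None:
            continue
        _, ni, strand, seq, res, w_start = best_result
        ref_name = index.names[ni]
        start = w_start + res["locations"][0][0]
        ref_positions, read_positions, matches, mismatches, ref_end = _cigar_to_pairs(
            res["cigar"], start
        )
        aligned_cols = matches + mismatches
        if aligned_cols == 0:
            continue
        alignments.append(
            Alignment(
                read_id=read.read_id,
                reference_id=ref_name,
                ref_start=start,
                ref_end=ref_end,
                strand=strand,
                identity=matches / aligned_cols,
                read_coverage=(read_positions.size + _n_inserted(res["cigar"]))
                / len(seq),
                read_seq=seq,
                ref_positions=ref_positions,
                read_positions=read_positions,
            )
        )
    return alignments


def _n_inserted(cigar: str) -> int:
    n_ins = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "I":
                n_ins += int(num)
            num = ""
    return n_ins


def write_sam(
    alignments: Sequence[Alignment],
    references: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write alignments as SAM with explicit =/X CIGAR operations.

    The emitted records are lossless for pileup purposes: reading them
    back with :func:`read_sam` reproduces identity, coverage and matched
    columns.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in sorted(references):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(references[name])}\n")
        for aln in alignments:
            ref = references[aln.reference_id].upper()
            cigar_parts: list[tuple[int, str]] = []

            def emit(op: str, n: int = 1) -> None:
                if cigar_parts and cigar_parts[-1][1] == op:
                    cigar_parts[-1] = (cigar_parts[-1][0] + n, op)
                else:
                    cigar_parts.append((n, op))

            read_seq = aln.read_seq.upper()
            first_q = int(aln.read_positions[0])
            last_q = int(aln.read_positions[-1])
            if first_q > 0:
                emit("S", first_q)
            prev_r = prev_q = None
            for rp, qp in zip(aln.ref_positions.tolist(),
                              aln.read_positions.tolist()):
                if prev_r is not None:
                    if qp - prev_q > 1:
                        emit("I", qp - prev_q - 1)
                    if rp - prev_r > 1:
                        emit("D", rp - prev_r - 1)
                emit("=" if read_seq[qp] == ref[rp] else "X")
                prev_r, prev_q = rp, qp
            if last_q < len(read_seq) - 1:
                emit("S", len(read_seq) - 1 - last_q)
            cigar = "".join(f"{n}{op}" for n, op in cigar_parts)
            flag = 16 if aln.strand == "-" else 0
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.reference_id}\t"
                f"{aln.ref_start + 1}\t60\t{cigar}\t*\t0\t0\t{read_seq}\t*\n"
            )


def filter_alignments(
    alignments: Iterable[Alignment],
    min_identity: float = 0.8,
    min_read_coverage: float = 0.8,
) -> list[Alignment]:
    """Keep alignments meeting both thresholds (inclusive, >=)."""
    return [
        a
        for a in alignments
        if a.identity >= min_identity and a.read_coverage >= min_read_coverage
    ]


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    """Per-position A/C/G/T counts on the forward reference strand."""

    reference_id: str
    counts: np.ndarray  # shape (4, L), rows in ACGT order

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tT\tdepth\n")
            depth = self.depth
            for i in range(self.length):
                a, c, g, t = (int(x) for x in self.counts[:, i])
                fh.write(f"{i}\t{a}\t{c}\t{g}\t{t}\t{int(depth[i])}\n")


def build_pileup(
    alignments: Iterable[Alignment],
    reference_id: str,
    reference_length: int,
) -> Pileup:
    """Accumulate every aligned non-gap base into per-position counts.

    Reverse-strand reads contribute on the forward reference strand
    (their stored sequence is already reference-oriented).  Non-ACGT read
    bases (Ns) are skipped.
    """
    counts = np.zeros(4 * reference_length, dtype=np.int32)
    for aln in alignments:
        if aln.reference_id != reference_id:
            continue
        if aln.ref_positions.size == 0:
            continue
        if aln.ref_positions[-1] >= reference_length or aln.ref_positions[0] < 0:
            raise ValueError(
                f"alignment of {aln.read_id} outside reference bounds"
            )
        seq_bytes = aln.read_seq.upper().encode()
        base_idx = np.frombuffer(seq_bytes.translate(_BASE_TO_IDX), dtype=np.uint8)
        valid = np.frombuffer(seq_bytes, dtype=np.uint8)
        is_acgt = (
            (valid == ord("A")) | (valid == ord("C")) |
            (valid == ord("G")) | (valid == ord("T"))
        )
        read_pos = aln.read_positions
        keep = is_acgt[read_pos]
        flat = base_idx[read_pos[keep]].astype(np.int64) * reference_length + \
            aln.ref_positions[keep]
        np.add.at(counts, flat, 1)
    return Pileup(reference_id=reference_id, counts=counts.reshape(4, reference_length))
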