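"""Alignment ingestion, the 80/80 rule, the internal mapper, and pileups."""

import numpy as np
import pytest

from ventpop.mapping import (
    Alignment,
    ReferenceIndex,
    build_pileup,
    filter_alignments,
    map_reads_simple,
    read_sam,
    write_sam,
)
from ventpop.synth import Read, ReadSet, reverse_complement


def _readset(reads):
    return ReadSet(reads=list(reads), read_length_range=(1, 1000), mean_depth=0.0)


def _sam(tmp_path, records, refs=(("ref1", 500),)):
    lines = ["@HD\tVN:1.6"]
    for name, length in refs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(records)
    path = tmp_path / "fixture.sam"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSam:
    def test_perfect_match_eqx(self, tmp_path):
        seq = "A" * 100
        path = _sam(tmp_path, [f"r1\t0\tref1\t11\t60\t100=\t*\t0\t0\t{seq}\t*"])
        alns, n_unmapped = read_sam(path)
        assert n_unmapped == 0
        (a,) = alns
        assert a.identity == 1.0
        assert a.read_coverage == 1.0
        assert a.ref_start == 10
        assert a.ref_end == 110

    def test_soft_clip_coverage(self, tmp_path):
        seq = "C" * 100
        path = _sam(tmp_path, [f"r1\t0\tref1\t1\t60\t80=20S\t*\t0\t0\t{seq}\t*"])
        (a,), _ = read_sam(path)
        assert a.read_coverage == pytest.approx(0.8)
        assert a.identity == 1.0

    def test_mismatches_counted(self, tmp_path):
        seq = "G" * 100
        path = _sam(tmp_path, [f"r1\t0\tref1\t1\t60\t90=10X\t*\t0\t0\t{seq}\t*"])
        (a,), _ = read_sam(path)
        assert a.identity == pytest.approx(0.9)

    def test_unmapped_records_skipped_and_counted(self, tmp_path):
        recs = []
        for i in range(10):
            if i < 2:
                recs.append(f"u{i}\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*")
            else:
                recs.append(f"m{i}\t0\tref1\t{i * 10 + 1}\t60\t4=\t*\t0\t0\tACGT\t*")
        path = _sam(tmp_path, recs)
        alns, n_unmapped = read_sam(path)
        assert len(alns) == 8
        assert n_unmapped == 2

    def test_md_tag_identity(self, tmp_path):
        # 10M with one mismatch at offset 4 described by MD
        path = _sam(
            tmp_path,
            ["r1\t0\tref1\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\tMD:Z:4G5"],
        )
        (a,), _ = read_sam(path)
        assert a.identity == pytest.approx(0.9)

    def test_no_identity_information_is_an_error(self, tmp_path):
        path = _sam(tmp_path, ["r1\t0\tref1\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*"])
        with pytest.raises(ValueError, match="MD"):
            read_sam(path)


class TestEightyEighty:
    def _aln(self, identity, coverage):
        return Alignment(
            read_id="r", reference_id="ref", ref_start=0, ref_end=10,
            strand="+", identity=identity, read_coverage=coverage,
            read_seq="A" * 10, ref_positions=np.arange(10),
            read_positions=np.arange(10),
        )

    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [
            (0.81, 0.85, True),
            (0.79, 0.99, False),
            (0.80, 0.80, True),   # inclusive boundary
            (0.99, 0.79, False),
        ],
    )
    def test_thresholds(self, identity, coverage, kept):
        out = filter_alignments([self._aln(identity, coverage)])
        assert bool(out) is kept

    def test_monotone_and_idempotent(self):
        alns = [self._aln(i / 100, c / 100) for i in range(70, 100, 3)
                for c in range(70, 100, 3)]
        kept = filter_alignments(alns)
        assert filter_alignments(kept) == kept
        stricter = filter_alignments(alns, min_identity=0.9)
        assert set(map(id, stricter)) <= set(map(id, kept))


class TestSimpleMapper:
    def test_error_free_reads_map_to_true_origin(self, small_truth, small_reads):
        index = ReferenceIndex(small_truth.genomes)
        alns = {a.read_id: a for a in map_reads_simple(small_reads, index)}
        n_correct = 0
        for read in small_reads.reads:
            a = alns.get(read.read_id)
            if a and a.reference_id == read.genome and \
               abs(a.ref_start - read.start) <= 5:
                n_correct += 1
        assert n_correct / len(small_reads) >= 0.99

    def test_reverse_complement_read_maps_minus_strand(self, small_truth):
        genome = small_truth.genomes["genome00"]
        fwd = Read("f", genome[1000:1150], "I" * 150, "genome00", 0, 1000, "+")
        rev = Read("r", reverse_complement(genome[1000:1150]), "I" * 150,
                   "genome00", 0, 1000, "-")
        alns = map_reads_simple(_readset([fwd, rev]), small_truth.genomes)
        by_id = {a.read_id: a for a in alns}
        assert by_id["f"].strand == "+"
        assert by_id["r"].strand == "-"
        assert by_id["f"].ref_start == by_id["r"].ref_start == 1000

    def test_unrelated_read_does_not_pass_80_80(self, small_truth, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        read = Read("x", seq, "I" * 200, "", 0, 0, "+")
        alns = map_reads_simple(_readset([read]), small_truth.genomes)
        assert filter_alignments(alns) == []


class TestPileup:
    def test_single_perfect_alignment(self, small_truth):
        genome = small_truth.genomes["genome00"]
        read = Read("p", genome[200:300], "I" * 100, "genome00", 0, 200, "+")
        alns = map_reads_simple(_readset([read]), small_truth.genomes)
        pu = build_pileup(alns, "genome00", len(genome))
        depth = pu.depth
        assert depth[200:300].tolist() == [1] * 100
        assert depth.sum() == 100

    def test_overlap_adds(self, small_truth):
        genome = small_truth.genomes["genome00"]
        reads = [
            Read("a", genome[200:300], "I" * 100, "genome00", 0, 200, "+"),
            Read("b", genome[250:350], "I" * 100, "genome00", 0, 250, "+"),
        ]
        alns = map_reads_simple(_readset(reads), small_truth.genomes)
        pu = build_pileup(alns, "genome00", len(genome))
        assert pu.depth[250:300].tolist() == [2] * 50
        assert pu.depth[200:250].tolist() == [1] * 50

    def test_conservation_against_bruteforce_recount(self, small_truth,
                                                     small_reads):
        alns = map_reads_simple(small_reads, small_truth.genomes)
        genome = "genome01"
        pu = build_pileup(alns, genome, len(small_truth.genomes[genome]))
        # brute force: recount every aligned non-gap ACGT base per position
        expect = np.zeros(pu.length, dtype=int)
        total = 0
        for a in alns:
            if a.reference_id != genome:
                continue
            for rp, qp in a.aligned_pairs:
                if a.read_seq[qp].upper() in "ACGT":
                    expect[rp] += 1
                    total += 1
        assert np.array_equal(pu.depth, expect)
        assert pu.depth.sum() == total

    def test_out_of_bounds_alignment_fails(self):
        aln = Alignment(
            read_id="r", reference_id="ref", ref_start=95, ref_end=105,
            strand="+", identity=1.0, read_coverage=1.0, read_seq="A" * 10,
            ref_positions=np.arange(95, 105), read_positions=np.arange(10),
        )
        with pytest.raises(ValueError):
            build_pileup([aln], "ref", 100)


def test_mapper_and_sam_roundtrip_give_identical_pileups(
    small_truth, small_reads, tmp_path
):
    alns = map_reads_simple(small_reads, small_truth.genomes)
    sam_path = tmp_path / "roundtrip.sam"
    write_sam(alns, small_truth.genomes, sam_path)
    alns2, n_unmapped = read_sam(sam_path)
    assert n_unmapped == 0
    for genome, seq in small_truth.genomes.items():
        p1 = build_pileup(alns, genome, len(seq))
        p2 = build_pileup(alns2, genome, len(seq))
        assert np.array_equal(p1.counts, p2.counts)
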