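"""Generator contracts: determinism, planted omega, islands, GC, reads."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest

from ventpop.dnds import STOP_CODONS, potential_sites, translate_codon
from ventpop.synth import (
    CommunityConfig,
    generate_community,
    reverse_complement,
    simulate_reads,
)


def _recount_omega(truth, gene_class):
    """Independent oracle: reclassify every planted substitution by codon
    table against the base genome and form the class-level rate ratio."""
    syn = non = 0
    s_pot = n_pot = 0.0
    genes = {g.gene_id: g for g in truth.genes}
    for gene in truth.genes:
        if gene.gene_class != gene_class:
            continue
        seq = truth.genomes[gene.genome][gene.start : gene.end]
        coding = reverse_complement(seq) if gene.strand == "-" else seq
        for cod in codons_of(coding)[1:-1]:
            s, n = potential_sites(cod)
            s_pot += s
            n_pot += n
    for site in truth.sites:
        gene = genes[site.gene_id]
        if gene.gene_class != gene_class:
            continue
        seq = truth.genomes[gene.genome][gene.start : gene.end]
        coding = reverse_complement(seq) if gene.strand == "-" else seq
        if gene.strand == "+":
            off = site.position - gene.start
            alt = site.alt_base
        else:
            off = gene.end - 1 - site.position
            alt = reverse_complement(site.alt_base)
        ci, cp = divmod(off, 3)
        codon = codons_of(coding)[ci]
        assert codon[cp] == coding[off]
        mutant = codon[:cp] + alt + codon[cp + 1 :]
        assert mutant not in STOP_CODONS
        if translate_codon(mutant) == translate_codon(codon):
            syn += 1
        else:
            non += 1
    assert syn + non == sum(
        1 for s in truth.sites if genes[s.gene_id].gene_class == gene_class
    ), "every planted substitution must classify as syn or nonsyn"
    return (non / n_pot) / (syn / s_pot)


def codons_of(coding):
    return [coding[i : i + 3] for i in range(0, len(coding), 3)]


def test_zero_polymorphism_rate_gives_identical_haplotypes():
    cfg = CommunityConfig(
        n_genomes=1, genes_per_genome=4, gene_length_nt=300,
        per_site_polymorphism_rate=0.0, n_haplotypes=5, seed=1,
    )
    truth = generate_community(cfg)
    assert truth.sites == []
    for i in range(5):
        assert truth.haplotype("genome00", i) == truth.genomes["genome00"]


def test_seeded_determinism_byte_identical(tmp_path):
    cfg = CommunityConfig(n_genomes=1, genes_per_genome=5, gene_length_nt=300,
                          n_haplotypes=8, seed=9)
    for sub in ("a", "b"):
        truth = generate_community(dataclasses.replace(cfg))
        d = tmp_path / sub
        d.mkdir()
        truth.write_fasta(d / "g.fasta")
        truth.write_gff3(d / "g.gff3")
        truth.write_truth_tsvs(d / "truth")
        reads = simulate_reads(truth, 5.0, (100, 150), seed=7)
        reads.write_fastq(d / "r.fastq")
        reads.write_truth_tsv(d / "r.tsv")
    a, b = tmp_path / "a", tmp_path / "b"
    for f in sorted(a.rglob("*")):
        if f.is_file():
            assert f.read_bytes() == (b / f.relative_to(a)).read_bytes()


def test_planted_omega_recovered_by_independent_recount():
    cfg = CommunityConfig(
        n_genomes=1, genes_per_genome=60, gene_length_nt=999,
        intergenic_nt=60, n_haplotypes=20,
        planted_omega={"cohort": 0.2}, per_site_polymorphism_rate=0.02, seed=5,
    )
    truth = generate_community(cfg)
    omega = _recount_omega(truth, "cohort")
    assert omega == pytest.approx(0.2, rel=0.15)
    # the generator's own bookkeeping agrees with the oracle recount
    assert truth.true_omega_by_class["cohort"] == pytest.approx(omega, rel=1e-9)


def test_haplotypes_same_length_and_minority_variants(small_truth):
    t = small_truth
    for genome, seq in t.genomes.items():
        for i in range(t.config.n_haplotypes):
            assert len(t.haplotype(genome, i)) == len(seq)
    for site in t.sites:
        assert 1 <= len(site.carriers) <= (t.config.n_haplotypes - 1) // 2
        assert site.ref_base != site.alt_base
        assert t.genomes[site.genome][site.position] == site.ref_base


def test_genome_gc_close_to_target():
    cfg = CommunityConfig(n_genomes=1, genes_per_genome=100,
                          gene_length_nt=999, gc_fraction=0.45,
                          per_site_polymorphism_rate=0.0, n_haplotypes=1, seed=3)
    truth = generate_community(cfg)
    seq = truth.genomes["genome00"]
    assert len(seq) >= 100_000
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.45) <= 0.02


def test_read_lengths_and_depth(small_truth):
    reads = simulate_reads(small_truth, mean_depth=20.0,
                           read_len_range=(100, 200), seed=11)
    lo, hi = 100, 200
    total = 0
    for r in reads.reads:
        assert lo <= len(r.sequence) <= hi
        assert len(r.quality) == len(r.sequence)
        total += len(r.sequence)
    genome_total = sum(len(s) for s in small_truth.genomes.values())
    realized = total / genome_total
    assert realized == pytest.approx(20.0, rel=0.10)


def test_read_origin_matches_sequence(small_truth):
    reads = simulate_reads(small_truth, mean_depth=3.0,
                           read_len_range=(100, 150), seed=12)
    for r in reads.reads[:200]:
        hap = small_truth.haplotype(r.genome, r.haplotype)
        expect = hap[r.start : r.end]
        if r.strand == "-":
            expect = reverse_complement(expect)
        assert r.sequence == expect


def test_island_sampled_at_presence_fraction():
    cfg = CommunityConfig(
        n_genomes=1, genes_per_genome=100, gene_length_nt=999,
        per_site_polymorphism_rate=0.0, n_haplotypes=1,
        island_spec=[(0, 30_000, 40_000, 0.2)], seed=4,
    )
    truth = generate_community(cfg)
    reads = simulate_reads(truth, mean_depth=20.0, read_len_range=(100, 300),
                           seed=5)
    genome_len = len(truth.genomes["genome00"])
    island = range(30_000, 70_000)
    in_island = sum(1 for r in reads.reads if r.start in island)
    outside = len(reads.reads) - in_island
    island_rate = in_island / 40_000
    outside_rate = outside / (genome_len - 40_000)
    assert island_rate / outside_rate == pytest.approx(0.2, rel=0.2)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CommunityConfig(gene_length_nt=100).validate()  # not a codon multiple
    with pytest.raises(ValueError):
        CommunityConfig(island_spec=[(0, 0, 10, 0.0)]).validate()
    with pytest.raises(ValueError):
        truth = generate_community(CommunityConfig(seed=1))
        simulate_reads(truth, mean_depth=-1.0)
    with pytest.raises(ValueError):
        truth = generate_community(
            CommunityConfig(n_genomes=1, genes_per_genome=1,
                            gene_length_nt=300, intergenic_nt=10, seed=1)
        )
        simulate_reads(truth, 5.0, read_len_range=(100, 10_000))
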