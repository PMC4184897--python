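"""Codon site counting, consensus calling, pN/pS records and summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ventpop.dnds import (
    BASES,
    STOP_CODONS,
    call_consensus,
    dedupe,
    gene_dnds,
    histogram,
    observed_substitutions,
    potential_sites,
    summarize,
    translate_codon,
    DnDsRecord,
)
from ventpop.mapping import Pileup
from ventpop.synth import GeneModel


def _oracle_sites(codon):
    """Independent enumeration of all 9 single-base mutants."""
    syn = 0.0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if mut not in STOP_CODONS and translate_codon(mut) == translate_codon(codon):
            syn += 1 / 3
    return syn, 3.0 - syn


class TestPotentialSites:
    def test_met_has_no_synonymous_neighbours(self):
        assert potential_sites("ATG") == (0.0, 3.0)

    def test_phe_third_position(self):
        s, n = potential_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_all_61_sense_codons_match_enumeration(self):
        sense = [
            "".join(c) for c in itertools.product(BASES, repeat=3)
            if "".join(c) not in STOP_CODONS
        ]
        assert len(sense) == 61
        for codon in sense:
            assert potential_sites(codon) == pytest.approx(_oracle_sites(codon))
            s, n = potential_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            potential_sites("TAA")
        with pytest.raises(ValueError):
            potential_sites("ANG")


def _pileup_from_columns(columns):
    """columns: list of dicts base->count, one per reference position."""
    counts = np.zeros((4, len(columns)), dtype=np.int32)
    for i, col in enumerate(columns):
        for base, c in col.items():
            counts[BASES.index(base), i] = c
    return Pileup(reference_id="ref", counts=counts)


def _uniform_columns(seq, depth):
    return [{b: depth} for b in seq]


class TestConsensus:
    def test_majority_depth_and_tie_rules(self):
        pu = _pileup_from_columns([
            {"A": 4, "G": 1},          # depth 5, majority A
            {"A": 4},                  # depth 4 -> masked
            {"A": 3, "G": 3},          # tie -> masked
            {"C": 9}, {"G": 9}, {"T": 9},
        ])
        gene = GeneModel("ref", "g", 0, 6, "+", 0, "x")
        cons = call_consensus(pu, gene, min_depth=5)
        assert cons.codons == [None, "CGT"]
        assert cons.covered_nt_at_min_depth == 5  # tie column still has depth 6

    def test_minus_strand_reverse_complemented(self):
        # reference holds revcomp(ATGAAA) = TTTCAT
        pu = _pileup_from_columns(_uniform_columns("TTTCAT", 10))
        gene = GeneModel("ref", "g", 0, 6, "-", 0, "x")
        cons = call_consensus(pu, gene, min_depth=5)
        assert cons.codons == ["ATG", "AAA"]

    def test_gene_outside_reference_fails(self):
        pu = _pileup_from_columns(_uniform_columns("ACGACG", 10))
        with pytest.raises(ValueError):
            call_consensus(pu, GeneModel("ref", "g", 0, 9, "+", 0, "x"))


class TestObservedSubstitutions:
    def test_no_variants_no_substitutions(self):
        pu = _pileup_from_columns(_uniform_columns("TTTAAA", 10))
        gene = GeneModel("ref", "g", 0, 6, "+", 0, "x")
        cons = call_consensus(pu, gene)
        assert observed_substitutions(pu, cons) == (0, 0)

    def test_synonymous_variant_third_position(self):
        # consensus TTT (Phe); 3 reads carry C at position 3 -> TTC, Phe
        pu = _pileup_from_columns([{"T": 10}, {"T": 10}, {"T": 7, "C": 3}])
        gene = GeneModel("ref", "g", 0, 3, "+", 0, "x")
        cons = call_consensus(pu, gene)
        assert observed_substitutions(pu, cons) == (1, 0)

    def test_nonsynonymous_variant_first_position(self):
        # consensus TTT; 2 reads carry G at position 1 -> GTT, Val
        pu = _pileup_from_columns([{"T": 8, "G": 2}, {"T": 10}, {"T": 10}])
        gene = GeneModel("ref", "g", 0, 3, "+", 0, "x")
        cons = call_consensus(pu, gene)
        assert observed_substitutions(pu, cons) == (0, 1)

    def test_single_read_variant_ignored(self):
        pu = _pileup_from_columns([{"T": 9, "G": 1}, {"T": 10}, {"T": 10}])
        gene = GeneModel("ref", "g", 0, 3, "+", 0, "x")
        cons = call_consensus(pu, gene)
        assert observed_substitutions(pu, cons, min_variant_count=2) == (0, 0)

    def test_count_per_read_switch(self):
        pu = _pileup_from_columns([{"T": 7, "G": 3}, {"T": 10}, {"T": 10}])
        gene = GeneModel("ref", "g", 0, 3, "+", 0, "x")
        cons = call_consensus(pu, gene)
        assert observed_substitutions(pu, cons, count_per_read=True) == (0, 3)


class TestGeneDnDs:
    def _cons(self, codons, covered=300, depth=30.0):
        from ventpop.dnds import ConsensusGene

        return ConsensusGene("g", "+", codons,
                             [(3 * i, 3 * i + 1, 3 * i + 2)
                              for i in range(len(codons))],
                             covered, depth)

    def test_definition_arithmetic(self):
        # dnds = (N_obs/N_pot)/(S_obs/S_pot); with TTT*75: S_pot=25, N_pot=200
        cons = self._cons(["TTT"] * 75)
        rec = gene_dnds("g", cons, s_obs=2, n_obs=1)
        assert rec.s_pot == pytest.approx(25.0)
        assert rec.n_pot == pytest.approx(200.0)
        assert rec.dnds == pytest.approx((1 / 200.0) / (2 / 25.0))
        assert rec.included

    def test_site_count_conservation(self):
        cons = self._cons(["ATG", "TTT", None, "GGG"])
        rec = gene_dnds("g", cons, s_obs=1, n_obs=0)
        n_unmasked = 3
        assert rec.s_pot + rec.n_pot == pytest.approx(3 * n_unmasked)

    def test_short_coverage_excluded(self):
        rec = gene_dnds("g", self._cons(["TTT"] * 75, covered=99), 2, 1)
        assert not rec.included
        assert rec.exclusion_reason == "short_coverage"
        rec100 = gene_dnds("g", self._cons(["TTT"] * 75, covered=100), 2, 1)
        assert rec100.included

    def test_zero_synonymous_is_undefined(self):
        rec = gene_dnds("g", self._cons(["TTT"] * 75), s_obs=0, n_obs=3)
        assert rec.dnds is None
        assert rec.exclusion_reason == "undefined_ratio"


class TestDedupe:
    def _rec(self, gene_id, depth):
        return DnDsRecord(gene_id, 25, 200, 2, 1, 0.25, depth, 300)

    def test_higher_coverage_retained(self):
        a, b = self._rec("gA", 12.0), self._rec("gB", 7.0)
        dedupe([a, b], {"gA": "grp", "gB": "grp"})
        assert a.included and not b.included
        assert b.exclusion_reason == "redundant"

    def test_singleton_unchanged(self):
        a = self._rec("gA", 5.0)
        dedupe([a], {"gA": "grp"})
        assert a.included

    def test_depth_tie_breaks_to_smallest_id(self):
        a, b = self._rec("gB", 9.0), self._rec("gA", 9.0)
        dedupe([a, b], {"gA": "grp", "gB": "grp"})
        assert b.included and not a.included


class TestSummarize:
    def test_zero_variance(self):
        recs = [DnDsRecord(f"g{i}", 25, 200, 2, 1, 0.2, 10, 300)
                for i in range(5)]
        s = summarize(recs)
        assert s.mean_dnds == pytest.approx(0.2)
        assert s.ci95[0] == pytest.approx(0.2)
        assert s.ci95[1] == pytest.approx(0.2)

    def test_against_closed_form_t_interval(self):
        values = [0.12, 0.25, 0.31, 0.08, 0.44]
        recs = [DnDsRecord(f"g{i}", 25, 200, 2, 1, v, 10, 300)
                for i, v in enumerate(values)]
        s = summarize(recs)
        mean = np.mean(values)
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        t = stats.t.ppf(0.975, len(values) - 1)
        assert s.mean_dnds == pytest.approx(mean)
        assert s.ci95 == pytest.approx((mean - t * se, mean + t * se))
        assert s.n_genes_purifying == 5

    def test_purifying_subset_only_in_ci(self):
        values = [0.2, 0.3, 1.5, 2.0]
        recs = [DnDsRecord(f"g{i}", 25, 200, 2, 1, v, 10, 300)
                for i, v in enumerate(values)]
        s = summarize(recs)
        assert s.n_genes_purifying == 2
        assert s.mean_dnds == pytest.approx(1.0)

    def test_too_few_records_fails(self):
        with pytest.raises(ValueError):
            summarize([DnDsRecord("g", 25, 200, 2, 1, 0.2, 10, 300)])

    def test_histogram_binning(self):
        values = [0.05, 0.15, 0.95, 1.2, 1.7]
        recs = [DnDsRecord(f"g{i}", 25, 200, 2, 1, v, 10, 300)
                for i, v in enumerate(values)]
        edges, counts = histogram(recs)
        assert edges[1] - edges[0] == pytest.approx(0.1)
        assert edges[-1] - edges[-2] == pytest.approx(0.5)
        assert counts.sum() == 5


def test_zero_polymorphism_cohort_all_undefined(small_truth):
    """No variation in the pileup must never produce a selection signal."""
    from ventpop.dnds import compute_gene_records
    from ventpop.mapping import build_pileup, map_reads_simple
    from ventpop.synth import simulate_reads, CommunityConfig, generate_community
    import dataclasses

    cfg = dataclasses.replace(small_truth.config, per_site_polymorphism_rate=0.0,
                              seed=99)
    truth = generate_community(cfg)
    reads = simulate_reads(truth, 12.0, (100, 200), seed=100)
    alns = map_reads_simple(reads, truth.genomes)
    for genome, seq in truth.genomes.items():
        pu = build_pileup(alns, genome, len(seq))
        for rec in compute_gene_records(pu, truth.genes_of(genome)):
            assert rec.s_obs == 0 and rec.n_obs == 0
            assert rec.dnds is None
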