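"""Planted-truth validation experiments.

Self-contained experiments that exercise the whole pipeline against the
synthetic generator's ground truth: dN/dS parameter recovery on cohorts
planted at known omega, a viral-vs-cellular style two-cohort contrast,
type-I/power calibration of the difference-of-medians test, and planted
genomic-island recovery.  Both the test suite and the reproduction script
run these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import CommunityConfig, generate_community, simulate_reads
from .qc import filter_reads
from .mapping import ReferenceIndex, build_pileup, filter_alignments, map_reads_simple
from .dnds import DnDsSummary, compute_gene_records, summarize
from .enrichment import FunctionalProfile, diff_medians_test
from .islands import CoverageTrack, call_islands, coverage_track, smooth_track

__all__ = [
    "recover_cohort",
    "contrast_cohorts",
    "null_calibration",
    "planted_power",
    "island_recovery",
]


def _run_dnds(truth, depth: float, seed: int):
    reads = simulate_reads(truth, depth, (100, 300), error_rate=0.0, seed=seed)
    kept, _ = filter_reads(reads)
    alns = filter_alignments(map_reads_simple(kept, truth.genomes))
    records = []
    for genome_id in sorted(truth.genomes):
        pileup = build_pileup(alns, genome_id, len(truth.genomes[genome_id]))
        records.extend(
            compute_gene_records(pileup, truth.genes_of(genome_id))
        )
    return records


def recover_cohort(
    omega: float,
    n_genes: int = 100,
    gene_length_nt: int = 999,
    n_haplotypes: int = 20,
    depth: float = 30.0,
    seed: int = 0,
) -> DnDsSummary:
    """Full-pipeline dN/dS recovery of one cohort planted at ``omega``."""
    cfg = CommunityConfig(
        n_genomes=1,
        genes_per_genome=n_genes,
        gene_length_nt=gene_length_nt,
        intergenic_nt=100,
        n_haplotypes=n_haplotypes,
        planted_omega={"cohort": omega},
        per_site_polymorphism_rate=0.02,
        seed=seed,
    )
    truth = generate_community(cfg)
    records = _run_dnds(truth, depth, seed + 1)
    return summarize(records)


def contrast_cohorts(
    omega_a: float = 0.15,
    omega_b: float = 0.22,
    n_genes_per_class: int = 200,
    gene_length_nt: int = 999,
    n_haplotypes: int = 20,
    depth: float = 30.0,
    seed: int = 0,
) -> dict[str, DnDsSummary]:
    """Two gene classes planted at different omega in one community."""
    cfg = CommunityConfig(
        n_genomes=1,
        genes_per_genome=2 * n_genes_per_class,
        gene_length_nt=gene_length_nt,
        intergenic_nt=100,
        n_haplotypes=n_haplotypes,
        planted_omega={"class_a": omega_a, "class_b": omega_b},
        per_site_polymorphism_rate=0.02,
        seed=seed,
    )
    truth = generate_community(cfg)
    records = _run_dnds(truth, depth, seed + 1)
    out = {}
    for cls in ("class_a", "class_b"):
        out[cls] = summarize([r for r in records if r.gene_class == cls])
    return out


def _random_profile(
    rng: np.random.Generator,
    proportions: np.ndarray,
    size: int,
    name: str,
) -> FunctionalProfile:
    counts = rng.multinomial(size, proportions)
    return FunctionalProfile(
        metagenome_id=name,
        scheme="SEED",
        counts={f"cat{i:02d}": int(c) for i, c in enumerate(counts)},
        total_reads=size,
    )


def null_calibration(
    n_pairs: int = 500,
    n_categories: int = 20,
    profile_size: int = 10_000,
    sample_size: int = 5000,
    confidence: float = 0.95,
    repetitions: int = 150,
    null_experiments: int = 120,
    seed: int = 0,
) -> float:
    """Per-category false-positive rate over null profile pairs.

    Each pair draws two profiles from the same category distribution
    (itself drawn per pair), so any significant category is a false
    positive.  Returns the aggregate rate as a fraction.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for i in range(n_pairs):
        p = rng.dirichlet(np.full(n_categories, 5.0))
        prof_a = _random_profile(rng, p, profile_size, "A")
        prof_b = _random_profile(rng, p, profile_size, "B")
        results = diff_medians_test(
            prof_a,
            prof_b,
            sample_size=sample_size,
            confidence=confidence,
            repetitions=repetitions,
            null_experiments=null_experiments,
            seed=int(rng.integers(2**31)),
        )
        n_sig += sum(r.significant for r in results)
        n_tests += len(results)
    return n_sig / n_tests


def planted_power(
    n_pairs: int = 20,
    n_categories: int = 10,
    profile_size: int = 10_000,
    planted_fraction_a: float = 0.2,
    planted_fraction_b: float = 0.1,
    sample_size: int = 5000,
    confidence: float = 0.95,
    repetitions: int = 150,
    null_experiments: int = 120,
    seed: int = 0,
) -> float:
    """Detection rate for a category planted at 2x relative abundance."""
    rng = np.random.default_rng(seed)
    rest = n_categories - 1
    p_a = np.array([planted_fraction_a] + [(1 - planted_fraction_a) / rest] * rest)
    p_b = np.array([planted_fraction_b] + [(1 - planted_fraction_b) / rest] * rest)
    detected = 0
    for i in range(n_pairs):
        prof_a = _random_profile(rng, p_a, profile_size, "A")
        prof_b = _random_profile(rng, p_b, profile_size, "B")
        results = diff_medians_test(
            prof_a,
            prof_b,
            sample_size=sample_size,
            confidence=confidence,
            repetitions=repetitions,
            null_experiments=null_experiments,
            seed=int(rng.integers(2**31)),
        )
        target = next(r for r in results if r.category == "cat00")
        if target.significant and target.direction == "A":
            detected += 1
    return detected / n_pairs


@dataclass
class IslandRecovery:
    genome_length: int
    true_start: int
    true_end: int
    n_islands: int
    called_start: int | None
    called_end: int | None
    boundary_error: int | None
    n_islands_uniform: int


def island_recovery(
    island_start: int = 300_000,
    island_length: int = 40_000,
    presence_fraction: float = 0.2,
    depth: float = 20.0,
    window: int = 50_000,
    target_genome_length: int = 1_000_000,
    seed: int = 0,
) -> IslandRecovery:
    """Plant a low-presence island in a ~1-Mb genome and recover it.

    Coverage comes from the simulated reads' true origin intervals (the
    recruitment-coords ingestion path); the same genome without an island
    is scanned as the uniform control.
    """
    per_gene = 999 + 100
    n_genes = (target_genome_length - 100) // per_gene

    def _community(island_spec):
        return generate_community(
            CommunityConfig(
                n_genomes=1,
                genes_per_genome=n_genes,
                gene_length_nt=999,
                intergenic_nt=100,
                n_haplotypes=1,
                planted_omega={"cohort": 1.0},
                per_site_polymorphism_rate=0.0,
                island_spec=island_spec,
                seed=seed,
            )
        )

    truth = _community([(0, island_start, island_length, presence_fraction)])
    genome_len = len(truth.genomes["genome00"])
    reads = simulate_reads(truth, depth, (100, 300), seed=seed + 1)
    raw = coverage_track(
        [(r.start, r.end) for r in reads.reads], genome_len
    ).astype(float)
    track = CoverageTrack("genome00", raw, window=window)
    islands = call_islands(track, rel_threshold=0.5, min_length=10_000)

    truth_u = _community([])
    reads_u = simulate_reads(truth_u, depth, (100, 300), seed=seed + 2)
    raw_u = coverage_track(
        [(r.start, r.end) for r in reads_u.reads], genome_len
    ).astype(float)
    islands_u = call_islands(
        CoverageTrack("genome00", raw_u, window=window),
        rel_threshold=0.5,
        min_length=10_000,
    )

    true_end = island_start + island_length
    called_start = called_end = boundary_error = None
    if islands:
        best = min(
            islands,
            key=lambda isl: abs((isl.start + isl.end) // 2
                                - (island_start + true_end) // 2),
        )
        called_start, called_end = best.start, best.end
        boundary_error = max(
            abs(called_start - island_start), abs(called_end - true_end)
        )
    return IslandRecovery(
        genome_length=genome_len,
        true_start=island_start,
        true_end=true_end,
        n_islands=len(islands),
        called_start=called_start,
        called_end=called_end,
        boundary_error=boundary_error,
        n_islands_uniform=len(islands_u),
    )
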