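"""Per-gene population dN/dS (pN/pS) from read pileups.

Selection pressure on genes in an environmental gene pool is estimated by
mapping metagenomic reads to reference genomes, calling a majority-rule
consensus per gene, and comparing the observed synonymous/nonsynonymous
polymorphisms to the number of synonymous/nonsynonymous sites available in
the consensus codons (Nei-Gojobori-style site counting).  Because reads are
drawn from a mixed population rather than two diverged lineages, the ratio
is an uncorrected polymorphism ratio (pN/pS): no multiple-hit correction is
applied and no inference about fixation is made.  Values below 1 indicate
purifying selection, above 1 diversifying selection.

Rules applied (all configurable):

* positions with depth < 5 are masked, and a codon with any masked position
  is dropped from both the potential-site and the observed tallies;
* a gene needs >= 100 nt at >= 5X depth to be included;
* a non-consensus base must be seen at least twice to count as a
  polymorphism (guards single-read sequencing error);
* genes with zero synonymous polymorphisms have an undefined ratio and are
  excluded from cohort means (their count is reported);
* redundant gene groups keep only the member with the highest coverage;
* the cohort 95% confidence interval is a Student-t interval over the
  genes with dN/dS < 1 (the purifying-selection subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "BASES",
    "STOP_CODONS",
    "translate_codon",
    "potential_sites",
    "ConsensusGene",
    "DnDsRecord",
    "DnDsSummary",
    "call_consensus",
    "observed_substitutions",
    "gene_dnds",
    "compute_gene_records",
    "dedupe",
    "summarize",
    "histogram",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Bacterial/archaeal genetic code (translation table 11).
_TABLE11 = unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)
_AA = dict(_TABLE11.forward_table)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _AA[codon]


def _potential_sites_uncached(codon: str) -> tuple[float, float]:
    syn = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            # A change to a stop codon counts as nonsynonymous, which keeps
            # syn + nonsyn == 3 per codon position triplet.
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def potential_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each of the three positions contributes (synonymous single-base
    neighbours)/3 synonymous sites; the remainder of the position's one
    site is nonsynonymous, so the two counts always sum to 3.

    Raises ``ValueError`` for stop codons or codons containing ambiguous
    characters; callers skip such codons and tally them as diagnostics.
    """
    codon = codon.upper()
    cached = _SITE_CACHE.get(codon)
    if cached is not None:
        return cached
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no site counts: {codon}")
    result = _potential_sites_uncached(codon)
    _SITE_CACHE[codon] = result
    return result


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

MASKED = None  # sentinel for codons dropped by depth/tie masking


@dataclass
class ConsensusGene:
    """Majority-rule consensus of one gene, in coding orientation.

    ``codons[i]`` is a 3-mer string, or ``None`` (masked) when any of the
    three positions has depth below the threshold or a tied majority.
    ``positions[i]`` holds the three reference coordinates of codon ``i``
    in coding order (descending for minus-strand genes).
    """

    gene_id: str
    strand: str
    codons: list[str | None]
    positions: list[tuple[int, int, int]]
    covered_nt_at_min_depth: int
    mean_depth: float


def _majority_base(column: np.ndarray, min_depth: int) -> str | None:
    depth = int(column.sum())
    if depth < min_depth:
        return None
    top = int(column.max())
    winners = np.flatnonzero(column == top)
    if winners.size != 1:
        return None  # tie -> masked
    return BASES[int(winners[0])]


def call_consensus(pileup, gene, min_depth: int = 5) -> ConsensusGene:
    """Call the majority-rule consensus codons of ``gene`` from a pileup.

    ``gene`` needs ``start``/``end`` (0-based half-open reference
    coordinates), ``strand`` ('+'/'-') and ``gene_id`` attributes, with
    ``end - start`` divisible by 3.  Minus-strand genes are
    reverse-complemented into coding orientation before codon assembly.
    Positions with depth below ``min_depth``, or without a unique majority
    base, are masked; any codon containing a masked position is dropped.
    """
    start, end = gene.start, gene.end
    if start < 0 or end > pileup.length:
        raise ValueError(
            f"gene {gene.gene_id} [{start}, {end}) outside reference "
            f"{pileup.reference_id} of length {pileup.length}"
        )
    if (end - start) % 3 != 0:
        raise ValueError(f"gene {gene.gene_id} length not divisible by 3")

    counts = pileup.counts[:, start:end]  # (4, L)
    depths = counts.sum(axis=0)
    covered = int((depths >= min_depth).sum())
    mean_depth = float(depths.mean()) if end > start else 0.0

    ref_positions = list(range(start, end))
    bases = [_majority_base(counts[:, i], min_depth) for i in range(end - start)]
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) if b else None for b in reversed(bases)]
        ref_positions = ref_positions[::-1]

    codons: list[str | None] = []
    positions: list[tuple[int, int, int]] = []
    for i in range(0, len(bases), 3):
        triple = bases[i : i + 3]
        positions.append(tuple(ref_positions[i : i + 3]))
        codons.append(None if any(b is None for b in triple) else "".join(triple))
    return ConsensusGene(
        gene_id=gene.gene_id,
        strand=gene.strand,
        codons=codons,
        positions=positions,
        covered_nt_at_min_depth=covered,
        mean_depth=mean_depth,
    )


# ---------------------------------------------------------------------------
# observed substitutions
# ---------------------------------------------------------------------------

def observed_substitutions(
    pileup,
    consensus: ConsensusGene,
    min_depth: int = 5,
    min_variant_count: int = 2,
    count_per_read: bool = False,
) -> tuple[int, int]:
    """Count observed synonymous and nonsynonymous polymorphisms.

    A polymorphism is a non-consensus base at an unmasked position seen at
    least ``min_variant_count`` times; it is classified by substituting it
    into the consensus codon (the other two positions taken from the
    consensus).  By default each distinct variant base counts once per
    position; ``count_per_read=True`` instead adds its read count.
    """
    s_obs = 0
    n_obs = 0
    minus = consensus.strand == "-"
    for codon, pos3 in zip(consensus.codons, consensus.positions):
        if codon is None or codon in STOP_CODONS:
            continue
        aa = translate_codon(codon)
        for cpos in range(3):
            ref_pos = pos3[cpos]
            column = pileup.counts[:, ref_pos]
            cons_base = codon[cpos]
            for bi, base in enumerate(BASES):
                count = int(column[bi])
                if count < min_variant_count:
                    continue
                coding_base = base.translate(_COMPLEMENT) if minus else base
                if coding_base == cons_base:
                    continue
                mutant = codon[:cpos] + coding_base + codon[cpos + 1 :]
                weight = count if count_per_read else 1
                if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                    s_obs += weight
                else:
                    n_obs += weight
    return s_obs, n_obs


# ---------------------------------------------------------------------------
# per-gene record and cohort summary
# ---------------------------------------------------------------------------

@dataclass
class DnDsRecord:
    gene_id: str
    s_pot: float
    n_pot: float
    s_obs: int
    n_obs: int
    dnds: float | None  # None == undefined (no synonymous polymorphism)
    mean_depth: float
    covered_nt_at_min_depth: int
    n_skipped_codons: int = 0
    included: bool = True
    exclusion_reason: str = "none"  # none|short_coverage|undefined_ratio|redundant
    gene_class: str | None = None

    @property
    def defined(self) -> bool:
        return self.dnds is not None


def gene_dnds(
    gene_id: str,
    consensus: ConsensusGene,
    s_obs: int,
    n_obs: int,
    min_covered_nt: int = 100,
    gene_class: str | None = None,
) -> DnDsRecord:
    """Assemble the per-gene record: site counts, ratio and inclusion flags."""
    s_pot = 0.0
    n_pot = 0.0
    skipped = 0
    for codon in consensus.codons:
        if codon is None:
            continue
        try:
            s, n = potential_sites(codon)
        except ValueError:
            skipped += 1
            continue
        s_pot += s
        n_pot += n

    dnds: float | None
    if s_obs == 0 or s_pot == 0 or n_pot == 0:
        dnds = None
    else:
        dnds = (n_obs / n_pot) / (s_obs / s_pot)

    record = DnDsRecord(
        gene_id=gene_id,
        s_pot=s_pot,
        n_pot=n_pot,
        s_obs=s_obs,
        n_obs=n_obs,
        dnds=dnds,
        mean_depth=consensus.mean_depth,
        covered_nt_at_min_depth=consensus.covered_nt_at_min_depth,
        n_skipped_codons=skipped,
        gene_class=gene_class,
    )
    if consensus.covered_nt_at_min_depth < min_covered_nt:
        record.included = False
        record.exclusion_reason = "short_coverage"
    elif dnds is None:
        record.included = False
        record.exclusion_reason = "undefined_ratio"
    return record


def compute_gene_records(
    pileup,
    genes: Iterable,
    min_depth: int = 5,
    min_variant_count: int = 2,
    min_covered_nt: int = 100,
    count_per_read: bool = False,
) -> list[DnDsRecord]:
    """Run consensus -> observed -> record for every gene on one reference."""
    records = []
    for gene in genes:
        cons = call_consensus(pileup, gene, min_depth=min_depth)
        s_obs, n_obs = observed_substitutions(
            pileup,
            cons,
            min_depth=min_depth,
            min_variant_count=min_variant_count,
            count_per_read=count_per_read,
        )
        records.append(
            gene_dnds(
                gene.gene_id,
                cons,
                s_obs,
                n_obs,
                min_covered_nt=min_covered_nt,
                gene_class=getattr(gene, "gene_class", None),
            )
        )
    return records


def dedupe(
    records: Sequence[DnDsRecord],
    redundancy_map: Mapping[str, object] | None,
) -> list[DnDsRecord]:
    """Within each redundancy group keep only the highest-coverage gene.

    ``redundancy_map`` maps gene_id -> group key; genes absent from the map
    are singletons.  Depth ties break to the lexicographically smallest
    gene_id.  Losers keep their values but are flagged
    ``exclusion_reason='redundant'``.
    """
    if not redundancy_map:
        return list(records)
    groups: dict[object, list[DnDsRecord]] = {}
    for rec in records:
        key = redundancy_map.get(rec.gene_id)
        if key is not None:
            groups.setdefault(key, []).append(rec)
    for members in groups.values():
        eligible = [r for r in members if r.included]
        if len(eligible) < 2:
            continue
        # highest coverage wins; depth ties break to the smallest gene_id
        winner = min(eligible, key=lambda r: (-r.mean_depth, r.gene_id))
        for rec in eligible:
            if rec is not winner:
                rec.included = False
                rec.exclusion_reason = "redundant"
    return list(records)


@dataclass
class DnDsSummary:
    n_genes: int
    n_undefined: int
    mean_dnds: float
    ci95: tuple[float, float]
    n_genes_purifying: int


def summarize(
    records: Sequence[DnDsRecord],
    alpha: float = 0.05,
) -> DnDsSummary:
    """Cohort mean and t-based CI over the purifying (dN/dS < 1) subset."""
    values = np.array([r.dnds for r in records if r.included and r.defined], float)
    n_undefined = sum(1 for r in records if r.exclusion_reason == "undefined_ratio")
    if values.size < 2:
        raise ValueError("need at least 2 included, defined dN/dS records")
    purifying = values[values < 1.0]
    mean = float(values.mean())
    if purifying.size >= 2:
        pm = float(purifying.mean())
        se = float(purifying.std(ddof=1)) / math.sqrt(purifying.size)
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, purifying.size - 1))
        ci = (pm - tcrit * se, pm + tcrit * se)
    elif purifying.size == 1:
        ci = (float(purifying[0]), float(purifying[0]))
    else:
        ci = (math.nan, math.nan)
    return DnDsSummary(
        n_genes=int(values.size),
        n_undefined=int(n_undefined),
        mean_dnds=mean,
        ci95=ci,
        n_genes_purifying=int(purifying.size),
    )


def histogram(records: Sequence[DnDsRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of included ratios: 0.1-wide bins up to 1, then 0.5-wide.

    Returns ``(edges, counts)``; the last bin is extended to cover the
    maximum observed value.
    """
    values = np.array([r.dnds for r in records if r.included and r.defined], float)
    top = max(2.0, float(values.max()) if values.size else 2.0)
    edges = list(np.round(np.arange(0.0, 1.0, 0.1), 10)) + list(
        np.arange(1.0, top + 0.5, 0.5)
    )
    edges = np.asarray(edges, float)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts
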