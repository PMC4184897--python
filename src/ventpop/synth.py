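"""Seeded synthetic vent community with planted ground truth.

Generates a small multi-genome community (bacterial/archaeal chromosomes
with codon-structured genes), a haplotype population carrying synonymous
and nonsynonymous polymorphisms at per-class target dN/dS values, planted
low-presence genomic islands, provirus regions and mobile-element genes,
and 454-style single-end reads (~100-300 nt) — together with machine-
readable truth tables so every downstream stage of the pipeline can be
tested without any external data.

Population model
----------------
Each genome has ``n_haplotypes`` full-length variants.  Polymorphisms are
planted per gene as site-level biallelic variants: a site gets a derived
base carried by a minority subset of haplotypes (carrier frequency uniform
in [0.20, 0.45] by default) so the majority-rule consensus always equals
the base genome.  The number of synonymous vs nonsynonymous sites per gene
is chosen so that the class-level ratio

    (nonsyn sites / nonsyn potential) / (syn sites / syn potential)

equals the class target omega up to rounding.  At most one polymorphic
site is planted per codon, start and stop codons are left intact, and no
planted change creates an internal stop codon.  Intergenic DNA carries no
polymorphism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import dnds as _dnds
from .dnds import BASES, STOP_CODONS, potential_sites, translate_codon

__all__ = [
    "CommunityConfig",
    "GeneModel",
    "PolymorphicSite",
    "CommunityTruth",
    "Read",
    "ReadSet",
    "generate_community",
    "simulate_reads",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CommunityConfig:
    """Parameters of the synthetic community.

    ``planted_omega`` maps gene class names (e.g. ``"cellular"``,
    ``"viral_amg"``) to the target per-class dN/dS; genes cycle through the
    classes in sorted order.  ``island_spec`` entries are
    ``(genome_index, start, length, presence_fraction)``;
    ``provirus_spec`` entries are ``(genome_index, start, length)``.
    """

    n_genomes: int = 2
    genes_per_genome: int = 20
    gene_length_nt: int = 300
    intergenic_nt: int = 100
    gc_fraction: float = 0.45
    n_haplotypes: int = 20
    planted_omega: dict[str, float] = field(
        default_factory=lambda: {"cellular": 0.22, "viral_amg": 0.15}
    )
    per_site_polymorphism_rate: float = 0.02
    island_spec: list[tuple[int, int, int, float]] = field(default_factory=list)
    mge_gene_fraction: float = 0.0
    provirus_spec: list[tuple[int, int, int]] = field(default_factory=list)
    carrier_freq_range: tuple[float, float] = (0.20, 0.45)
    seed: int = 0

    def validate(self) -> None:
        if self.gene_length_nt % 3 != 0:
            raise ValueError("gene_length_nt must be a multiple of 3")
        if self.gene_length_nt < 9:
            raise ValueError("gene_length_nt must allow start + body + stop")
        for frac in (
            self.gc_fraction,
            self.per_site_polymorphism_rate,
            self.mge_gene_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0, 1]: {frac}")
        for spec in self.island_spec:
            if not 0.0 < spec[3] <= 1.0:
                raise ValueError("island presence_fraction must be in (0, 1]")
        if self.n_haplotypes < 1 or self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ValueError("counts must be positive")
        if not all(omega > 0 for omega in self.planted_omega.values()):
            raise ValueError("planted_omega values must be positive")
        lo, hi = self.carrier_freq_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("carrier_freq_range must lie inside (0, 0.5)")

    @property
    def genome_length(self) -> int:
        per_gene = self.gene_length_nt + self.intergenic_nt
        return self.genes_per_genome * per_gene + self.intergenic_nt


@dataclass
class GeneModel:
    genome: str
    gene_id: str
    start: int  # 0-based half-open, reference coordinates
    end: int
    strand: str
    frame: int
    gene_class: str
    is_mge: bool = False


@dataclass
class PolymorphicSite:
    genome: str
    gene_id: str
    position: int  # reference coordinate of the variant base
    ref_base: str  # reference-strand bases
    alt_base: str
    kind: str  # 'syn' | 'nonsyn'
    carriers: tuple[int, ...]  # haplotype indices carrying the variant


@dataclass
class CommunityTruth:
    config: CommunityConfig
    genomes: dict[str, str]
    genes: list[GeneModel]
    sites: list[PolymorphicSite]
    islands: list[tuple[str, int, int, float]]  # genome, start, end, presence
    proviruses: list[tuple[str, int, int]]
    true_omega_by_gene: dict[str, float | None]
    true_omega_by_class: dict[str, float]

    _haplotype_cache: dict[tuple[str, int], str] = field(
        default_factory=dict, repr=False
    )

    def haplotype(self, genome: str, index: int) -> str:
        """Full-length haplotype sequence (base genome + carried variants)."""
        key = (genome, index)
        cached = self._haplotype_cache.get(key)
        if cached is not None:
            return cached
        seq = list(self.genomes[genome])
        for site in self.sites:
            if site.genome == genome and index in site.carriers:
                seq[site.position] = site.alt_base
        result = "".join(seq)
        self._haplotype_cache[key] = result
        return result

    def genes_of(self, genome: str) -> list[GeneModel]:
        return [g for g in self.genes if g.genome == genome]

    # -- writers ------------------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.genomes):
                fh.write(f">{name}\n")
                seq = self.genomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name in sorted(self.genomes):
                fh.write(f"##sequence-region {name} 1 {len(self.genomes[name])}\n")
            for g in self.genes:
                attrs = (
                    f"ID={g.gene_id};gene_class={g.gene_class};"
                    f"is_mge={'true' if g.is_mge else 'false'}"
                )
                fh.write(
                    "\t".join(
                        [
                            g.genome,
                            "ventpop-synth",
                            "CDS",
                            str(g.start + 1),  # GFF3 is 1-based inclusive
                            str(g.end),
                            ".",
                            g.strand,
                            str(g.frame),
                            attrs,
                        ]
                    )
                    + "\n"
                )

    def write_truth_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sites.tsv", "w") as fh:
            fh.write("genome\tgene_id\tposition\tref\talt\tkind\tcarriers\n")
            for s in self.sites:
                carriers = ",".join(map(str, s.carriers))
                fh.write(
                    f"{s.genome}\t{s.gene_id}\t{s.position}\t{s.ref_base}\t"
                    f"{s.alt_base}\t{s.kind}\t{carriers}\n"
                )
        with open(outdir / "gene_omega.tsv", "w") as fh:
            fh.write("gene_id\tgene_class\ttrue_omega\n")
            by_id = {g.gene_id: g for g in self.genes}
            for gene_id in sorted(self.true_omega_by_gene):
                omega = self.true_omega_by_gene[gene_id]
                txt = "NA" if omega is None else f"{omega:.6f}"
                fh.write(f"{gene_id}\t{by_id[gene_id].gene_class}\t{txt}\n")
        with open(outdir / "features.tsv", "w") as fh:
            fh.write("feature\tgenome\tstart\tend\tvalue\n")
            for genome, start, end, presence in self.islands:
                fh.write(f"island\t{genome}\t{start}\t{end}\t{presence}\n")
            for genome, start, end in self.proviruses:
                fh.write(f"provirus\t{genome}\t{start}\t{end}\t.\n")
            for g in self.genes:
                if g.is_mge:
                    fh.write(f"mge_gene\t{g.genome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", np.uint8), size=n, p=p)


_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i
_STOP_IDS = frozenset(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in STOP_CODONS
)


def _random_gene(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + random sense codons + stop, at roughly the requested GC."""
    n_body = length // 3 - 2
    chunks: list[bytes] = []
    need = n_body
    stop_ids = np.fromiter(_STOP_IDS, dtype=np.int64)
    while need > 0:
        n = need + 8
        arr = _random_bases(rng, 3 * n, gc).reshape(-1, 3)
        idx = _BYTE_TO_IDX[arr]
        ids = idx[:, 0].astype(np.int64) * 16 + idx[:, 1] * 4 + idx[:, 2]
        kept = arr[~np.isin(ids, stop_ids)][:need]
        chunks.append(kept.tobytes())
        need -= kept.shape[0]
    stop = ["TAA", "TGA", "TAG"][int(rng.integers(3))]
    return "ATG" + b"".join(chunks).decode() + stop


def _syn_options(codon: str) -> list[tuple[int, str]]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                out.append((pos, base))
    return out


def _nonsyn_options(codon: str) -> list[tuple[int, str]]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            # internal stop codons are never planted
            if mutant not in STOP_CODONS and translate_codon(mutant) != aa:
                out.append((pos, base))
    return out


def _plant_gene_sites(
    rng: np.random.Generator,
    gene: GeneModel,
    gene_seq: str,
    omega: float,
    rate: float,
    n_haplotypes: int,
    carrier_range: tuple[float, float],
    syn_carry: float,
) -> tuple[list[PolymorphicSite], int, int, float, float, float]:
    """Plant polymorphic sites in one gene; returns sites and bookkeeping.

    ``syn_carry`` is the fractional remainder of synonymous counts carried
    across genes (largest-remainder rounding at class level); the updated
    remainder is returned.
    """
    codons = [gene_seq[i : i + 3] for i in range(0, len(gene_seq), 3)]
    # plantable codons: exclude start and stop
    body = list(range(1, len(codons) - 1))
    s_pot = n_pot = 0.0
    for i in body:
        s, n = potential_sites(codons[i])
        s_pot += s
        n_pot += n
    n_coding_sites = 3 * len(body)
    k = int(rng.binomial(n_coding_sites, rate))
    k = min(k, len(body))  # one site per codon at most
    if k == 0:
        return [], 0, 0, s_pot, n_pot, syn_carry

    # probability a planted site is synonymous so the class ratio hits omega
    p_syn = 1.0 / (1.0 + omega * n_pot / s_pot)
    target = k * p_syn + syn_carry
    n_syn = int(math.floor(target))
    syn_carry = target - n_syn
    n_syn = min(n_syn, k)
    n_non = k - n_syn

    chosen = rng.choice(len(body), size=k, replace=False)
    chosen_codons = [body[i] for i in chosen]
    sites: list[PolymorphicSite] = []
    planted_syn = planted_non = 0
    kinds = ["syn"] * n_syn + ["nonsyn"] * n_non
    lo, hi = carrier_range
    for codon_idx, kind in zip(chosen_codons, kinds):
        codon = codons[codon_idx]
        options = _syn_options(codon) if kind == "syn" else _nonsyn_options(codon)
        if not options:
            # codon cannot host this kind (e.g. ATG/TGG have no synonymous
            # neighbour); try the other kind instead of dropping the site
            kind = "nonsyn" if kind == "syn" else "syn"
            options = _syn_options(codon) if kind == "syn" else _nonsyn_options(codon)
            if not options:
                continue
        pos_in_codon, alt_coding = options[int(rng.integers(len(options)))]
        # carriers: a minority subset so consensus stays the base genome
        freq = rng.uniform(lo, hi)
        n_carriers = max(1, int(round(freq * n_haplotypes)))
        n_carriers = min(n_carriers, max(1, (n_haplotypes - 1) // 2))
        carriers = tuple(
            sorted(int(c) for c in rng.choice(n_haplotypes, n_carriers, replace=False))
        )
        coding_offset = codon_idx * 3 + pos_in_codon
        if gene.strand == "+":
            ref_pos = gene.start + coding_offset
            ref_base = gene_seq[coding_offset]
            alt_base = alt_coding
        else:
            ref_pos = gene.end - 1 - coding_offset
            ref_base = gene_seq[coding_offset].translate(_COMPLEMENT)
            alt_base = alt_coding.translate(_COMPLEMENT)
        sites.append(
            PolymorphicSite(
                genome=gene.genome,
                gene_id=gene.gene_id,
                position=ref_pos,
                ref_base=ref_base,
                alt_base=alt_base,
                kind=kind,
                carriers=carriers,
            )
        )
        if kind == "syn":
            planted_syn += 1
        else:
            planted_non += 1
    return sites, planted_syn, planted_non, s_pot, n_pot, syn_carry


def generate_community(config: CommunityConfig) -> CommunityTruth:
    """Build genomes, gene models and the polymorphic haplotype population."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.planted_omega)

    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_index = 0
    for gi in range(config.n_genomes):
        name = f"genome{gi:02d}"
        parts: list[str] = []
        pos = 0
        inter = config.intergenic_nt
        gene_specs: list[tuple[int, int, str]] = []  # start, end, strand
        for gj in range(config.genes_per_genome):
            parts.append(_random_bases(rng, inter, config.gc_fraction).tobytes().decode())
            pos += inter
            strand = "+" if gj % 2 == 0 else "-"
            gene_seq = _random_gene(rng, config.gene_length_nt, config.gc_fraction)
            if strand == "-":
                parts.append(reverse_complement(gene_seq))
            else:
                parts.append(gene_seq)
            gene_specs.append((pos, pos + config.gene_length_nt, strand))
            pos += config.gene_length_nt
        parts.append(_random_bases(rng, inter, config.gc_fraction).tobytes().decode())
        genomes[name] = "".join(parts)

        n_mge = int(round(config.mge_gene_fraction * config.genes_per_genome))
        mge_ids = set(rng.choice(config.genes_per_genome, n_mge, replace=False))
        for gj, (start, end, strand) in enumerate(gene_specs):
            genes.append(
                GeneModel(
                    genome=name,
                    gene_id=f"gene{gene_index:05d}",
                    start=start,
                    end=end,
                    strand=strand,
                    frame=0,
                    gene_class=classes[gene_index % len(classes)],
                    is_mge=gj in mge_ids,
                )
            )
            gene_index += 1

    # plant population polymorphism gene by gene
    sites: list[PolymorphicSite] = []
    true_omega_by_gene: dict[str, float | None] = {}
    class_tallies = {
        c: {"syn": 0, "non": 0, "s_pot": 0.0, "n_pot": 0.0} for c in classes
    }
    syn_carry = {c: 0.5 for c in classes}  # start remainders mid-way
    for gene in genes:
        seq = genomes[gene.genome][gene.start : gene.end]
        coding = reverse_complement(seq) if gene.strand == "-" else seq
        omega = config.planted_omega[gene.gene_class]
        g_sites, n_syn, n_non, s_pot, n_pot, carry = _plant_gene_sites(
            rng,
            gene,
            coding,
            omega,
            config.per_site_polymorphism_rate,
            config.n_haplotypes,
            config.carrier_freq_range,
            syn_carry[gene.gene_class],
        )
        syn_carry[gene.gene_class] = carry
        sites.extend(g_sites)
        t = class_tallies[gene.gene_class]
        t["syn"] += n_syn
        t["non"] += n_non
        t["s_pot"] += s_pot
        t["n_pot"] += n_pot
        if n_syn > 0 and s_pot > 0 and n_pot > 0:
            true_omega_by_gene[gene.gene_id] = (n_non / n_pot) / (n_syn / s_pot)
        else:
            true_omega_by_gene[gene.gene_id] = None

    true_omega_by_class: dict[str, float] = {}
    for c, t in class_tallies.items():
        if t["syn"] > 0 and t["s_pot"] > 0 and t["n_pot"] > 0:
            true_omega_by_class[c] = (t["non"] / t["n_pot"]) / (t["syn"] / t["s_pot"])
        else:
            true_omega_by_class[c] = math.nan

    if config.per_site_polymorphism_rate > 0 and config.n_haplotypes >= 3 and not sites:
        raise ValueError(
            "impossible config: polymorphism requested but no site could be planted"
        )

    genome_names = sorted(genomes)
    islands = []
    for genome_idx, start, length, presence in config.island_spec:
        name = genome_names[genome_idx]
        if start + length > len(genomes[name]):
            raise ValueError("island extends beyond genome end")
        islands.append((name, start, start + length, presence))
    proviruses = []
    for genome_idx, start, length in config.provirus_spec:
        name = genome_names[genome_idx]
        if start + length > len(genomes[name]):
            raise ValueError("provirus extends beyond genome end")
        proviruses.append((name, start, start + length))

    return CommunityTruth(
        config=config,
        genomes=genomes,
        genes=genes,
        sites=sites,
        islands=islands,
        proviruses=proviruses,
        true_omega_by_gene=true_omega_by_gene,
        true_omega_by_class=true_omega_by_class,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str
    genome: str
    haplotype: int
    start: int  # 0-based start of the true origin on the reference
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class ReadSet:
    reads: list[Read]
    read_length_range: tuple[int, int]
    mean_depth: float

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tgenome\thaplotype\tstart\tend\tstrand\n")
            for r in self.reads:
                fh.write(
                    f"{r.read_id}\t{r.genome}\t{r.haplotype}\t{r.start}\t"
                    f"{r.end}\t{r.strand}\n"
                )


def simulate_reads(
    truth: CommunityTruth,
    mean_depth: float,
    read_len_range: tuple[int, int] = (100, 300),
    error_rate: float = 0.0,
    seed: int = 0,
    lowq_fraction: float = 0.0,
    base_phred: int = 38,
    lowq_phred: int = 15,
    region_weights: Sequence[tuple[str, int, int, float]] = (),
    id_prefix: str = "read",
) -> ReadSet:
    """Draw 454-style single-end reads uniformly from the haplotype pool.

    Start positions are weighted: planted island positions are sampled at
    ``presence_fraction`` times the background rate (emulating a region
    present in only a fraction of the population), and ``region_weights``
    can up- or down-weight further intervals.  A ``lowq_fraction`` of reads
    gets a uniformly low quality string so the QC stage has material to
    reject.  Qualities are Sanger Phred+33.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    min_len, max_len = read_len_range
    if min_len > max_len or min_len < 1:
        raise ValueError("invalid read length range")
    for name, seq in truth.genomes.items():
        if max_len > len(seq):
            raise ValueError(f"read length {max_len} exceeds genome {name}")

    rng = np.random.default_rng(seed)
    genome_names = sorted(truth.genomes)
    weights: dict[str, np.ndarray] = {}
    for name in genome_names:
        w = np.ones(len(truth.genomes[name]), dtype=float)
        weights[name] = w
    for genome, start, end, presence in truth.islands:
        weights[genome][start:end] *= presence
    for genome, start, end, factor in region_weights:
        weights[genome][start:end] *= factor

    totals = np.array([weights[n].sum() for n in genome_names])
    genome_p = totals / totals.sum()
    cum = {n: np.cumsum(weights[n]) for n in genome_names}

    total_len = sum(len(truth.genomes[n]) for n in genome_names)
    mean_len = (min_len + max_len) / 2.0
    n_reads = int(round(mean_depth * total_len / mean_len))
    n_hap = truth.config.n_haplotypes

    # draw all per-read randomness up front (vectorised, seed-stable)
    gidx = rng.choice(len(genome_names), size=n_reads, p=genome_p)
    lengths = rng.integers(min_len, max_len + 1, size=n_reads)
    start_u = rng.uniform(0.0, 1.0, size=n_reads)
    haps = rng.integers(n_hap, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    lowq = rng.random(n_reads) < lowq_fraction

    reads: list[Read] = []
    qual_cache: dict[tuple[int, int], str] = {}
    for i in range(n_reads):
        gname = genome_names[int(gidx[i])]
        glen = len(truth.genomes[gname])
        length = int(lengths[i])
        c = cum[gname]
        start = int(np.searchsorted(c, start_u[i] * c[-1], side="right"))
        start = min(start, glen - length)
        hap = int(haps[i])
        seq = truth.haplotype(gname, hap)[start : start + length]
        if error_rate > 0.0:
            n_err = rng.binomial(length, error_rate)
            if n_err:
                seq_list = list(seq)
                for pos in rng.choice(length, size=n_err, replace=False):
                    current = seq_list[pos]
                    alts = [b for b in BASES if b != current]
                    seq_list[pos] = alts[int(rng.integers(3))]
                seq = "".join(seq_list)
        if minus[i]:
            seq = reverse_complement(seq)
        phred = lowq_phred if lowq[i] else base_phred
        qkey = (phred, length)
        quality = qual_cache.get(qkey)
        if quality is None:
            quality = chr(phred + 33) * length
            qual_cache[qkey] = quality
        reads.append(
            Read(
                read_id=f"{id_prefix}{i:07d}",
                sequence=seq,
                quality=quality,
                genome=gname,
                haplotype=int(haps[i]),
                start=start,
                strand="-" if minus[i] else "+",
            )
        )
    return ReadSet(reads=reads, read_length_range=read_len_range, mean_depth=mean_depth)
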