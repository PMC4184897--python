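"""End-to-end pipeline: chain all stages into a reproducible report bundle.

In synthetic mode the pipeline generates a seeded community, simulates a
"cellular" and a "viral" read set (the viral set over-samples provirus
regions and mobile-element genes), then runs read QC, mapping with the
80/80 rule, per-gene pN/pS per gene class, category-enrichment and
unique-hit tallies (from truth-derived annotation tables), island
scanning, and the viral-subset filter, writing one report file per stage
plus a provenance record.  The same config and seed produce byte-identical
reports.

In file mode (``synthesize=False``) the QC/mapping/pN/pS stages run on a
supplied FASTQ, reference FASTA and GFF3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .synth import CommunityConfig, CommunityTruth, ReadSet, generate_community, simulate_reads
from .qc import QCParams, filter_reads, write_report
from .mapping import ReferenceIndex, build_pileup, filter_alignments, map_reads_simple
from .dnds import compute_gene_records, dedupe, histogram, summarize
from .enrichment import (
    BLAST6_COLUMNS,
    diff_medians_test,
    rank_metagenomes,
    tally_profile,
    tally_unique_hits,
)
from .islands import CoverageTrack, call_islands, smooth_track
from .subset import ContigRecord, contig_taxonomy, viral_subset

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "ventpop_run"
    seed: int = 0
    synthesize: bool = True

    # file-mode inputs (required when synthesize is False)
    reads_fastq: str | None = None
    references_fasta: str | None = None
    genes_gff3: str | None = None

    # synthetic community
    community: CommunityConfig = field(default_factory=CommunityConfig)
    mean_depth: float = 20.0
    read_len_range: tuple[int, int] = (100, 300)
    error_rate: float = 0.0
    lowq_fraction: float = 0.02
    viral_bias: float = 3.0  # provirus/MGE over-sampling in the viral read set

    # stage parameters (defaults are the study's stated values)
    qc: QCParams = field(default_factory=QCParams)
    min_identity: float = 0.8
    min_read_coverage: float = 0.8
    min_depth: int = 5
    min_variant_count: int = 2
    min_covered_nt: int = 100
    enrich_sample_size: int = 5000
    enrich_confidence: float = 0.95
    enrich_repetitions: int = 300
    enrich_null_experiments: int = 100
    island_window: int = 50_000
    island_rel_threshold: float = 0.5
    island_min_length: int = 10_000
    subset_min_coverage: float = 8.0
    contig_bin_size: int = 5000

    # stage toggles
    run_dnds: bool = True
    run_enrichment: bool = True
    run_islands: bool = True
    run_subset: bool = True


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _gene_category(gene) -> str:
    if gene.is_mge:
        return "mobile_elements"
    idx = int("".join(ch for ch in gene.gene_id if ch.isdigit()) or 0)
    return f"cat{idx % 8:02d}"


def _read_annotations(
    reads: ReadSet, truth: CommunityTruth
) -> tuple[list[dict], dict[str, str]]:
    """Truth-derived functional annotations and taxon labels per read.

    Synthetic stand-in for an external annotation service: a read is
    annotated with the category of the gene its origin midpoint falls in
    (provirus regions map to ``phage_provirus``), and with a coarse taxon
    derived from its origin.  Every 20th annotation row is given a
    failing e-value so threshold filtering is exercised.
    """
    gene_lookup = {}
    for gene in truth.genes:
        gene_lookup.setdefault(gene.genome, []).append(gene)
    provirus_by_genome: dict[str, list[tuple[int, int]]] = {}
    for genome, start, end in truth.proviruses:
        provirus_by_genome.setdefault(genome, []).append((start, end))
    genome_names = sorted(truth.genomes)

    rows: list[dict] = []
    taxa: dict[str, str] = {}
    for i, read in enumerate(reads.reads):
        mid = read.start + len(read.sequence) // 2
        in_provirus = any(
            s <= mid < e for s, e in provirus_by_genome.get(read.genome, ())
        )
        category = None
        for gene in gene_lookup.get(read.genome, ()):
            if gene.start <= mid < gene.end:
                category = _gene_category(gene)
                break
        if in_provirus:
            category = "phage_provirus"
        if category is not None:
            rows.append(
                {
                    "read_id": read.read_id,
                    "category": category,
                    "evalue": 1e-2 if i % 20 == 19 else 1e-10,
                    "identity": 0.9,
                }
            )
        if in_provirus:
            taxa[read.read_id] = "viral"
        elif category is not None:
            parity = genome_names.index(read.genome) % 2
            taxa[read.read_id] = "bacteria" if parity == 0 else "archaea"
        # intergenic, non-provirus reads stay unannotated
    return rows, taxa


def _hit_rows(reads: ReadSet, truth: CommunityTruth, kind: str) -> list[list]:
    """Synthetic BLAST outfmt-6 rows for reads overlapping planted features."""
    targets: list[tuple[str, int, int]] = []
    if kind == "prophage":
        targets = [(g, s, e) for g, s, e in truth.proviruses]
    else:
        targets = [
            (g.genome, g.start, g.end) for g in truth.genes if g.is_mge
        ]
    rows = []
    for read in reads.reads:
        mid = read.start + len(read.sequence) // 2
        for genome, start, end in targets:
            if read.genome == genome and start <= mid < end:
                rows.append(
                    [read.read_id, f"{kind}_ref", 95.0, len(read.sequence), 3, 0,
                     1, len(read.sequence), start + 1, end, 1e-10, 200.0]
                )
                break
    return rows


def _load_file_inputs(config: PipelineConfig):
    from Bio import SeqIO

    from .qc import read_fastq

    for label, path in (
        ("reads_fastq", config.reads_fastq),
        ("references_fasta", config.references_fasta),
        ("genes_gff3", config.genes_gff3),
    ):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input {label}: {path}")
    reads = read_fastq(config.reads_fastq)
    genomes = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(config.references_fasta, "fasta")
    }
    genes = []

    @dataclass
    class _Gene:
        genome: str
        gene_id: str
        start: int
        end: int
        strand: str
        frame: int
        gene_class: str = "all"
        is_mge: bool = False

    with open(config.genes_gff3) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("CDS", "gene"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            genes.append(
                _Gene(
                    genome=parts[0],
                    gene_id=attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                    frame=int(parts[7]) if parts[7].isdigit() else 0,
                    gene_class=attrs.get("gene_class", "all"),
                    is_mge=attrs.get("is_mge") == "true",
                )
            )
    return reads, genomes, genes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a summary dict (also written as ``report.json``).  With a
    fixed config and seed the bundle is byte-identical across runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    report: dict = {"seed": config.seed, "version": __version__}

    # ---- stage: inputs -----------------------------------------------------
    if config.synthesize:
        community_cfg = dataclasses.replace(config.community, seed=config.seed)
        truth = generate_community(community_cfg)
        truth.write_fasta(outdir / "genomes.fasta")
        truth.write_gff3(outdir / "genes.gff3")
        truth.write_truth_tsvs(outdir / "truth")
        weights = [
            (g, s, e, config.viral_bias) for g, s, e in truth.proviruses
        ] + [
            (g.genome, g.start, g.end, config.viral_bias)
            for g in truth.genes
            if g.is_mge
        ]
        readsets = {
            "cellular": simulate_reads(
                truth,
                config.mean_depth,
                config.read_len_range,
                error_rate=config.error_rate,
                seed=config.seed * 1000 + 1,
                lowq_fraction=config.lowq_fraction,
                id_prefix="cell",
            ),
            "viral": simulate_reads(
                truth,
                config.mean_depth,
                config.read_len_range,
                error_rate=config.error_rate,
                seed=config.seed * 1000 + 2,
                lowq_fraction=config.lowq_fraction,
                region_weights=weights,
                id_prefix="vir",
            ),
        }
        genomes = truth.genomes
        genes = truth.genes
    else:
        reads, genomes, genes = _load_file_inputs(config)
        truth = None
        readsets = {"input": reads}

    for name, rs in readsets.items():
        rs.write_fastq(outdir / f"reads_{name}.fastq")

    # ---- stage: QC ---------------------------------------------------------
    kept_sets: dict[str, ReadSet] = {}
    for name, rs in readsets.items():
        kept, rejected = filter_reads(rs, config.qc)
        write_report(rejected, outdir / f"qc_rejected_{name}.tsv")
        kept_sets[name] = kept
        log_lines.append(
            f"qc\t{name}\tkept={len(kept)}\tremoved={len(rejected)}"
        )
        report[f"qc_kept_{name}"] = len(kept)
        report[f"qc_removed_{name}"] = len(rejected)

    # ---- stage: mapping ----------------------------------------------------
    index = ReferenceIndex(genomes)
    mapped: dict[str, list] = {}
    for name, rs in kept_sets.items():
        alns = map_reads_simple(rs, index)
        kept_alns = filter_alignments(
            alns, config.min_identity, config.min_read_coverage
        )
        mapped[name] = kept_alns
        log_lines.append(
            f"map\t{name}\tmapped={len(alns)}\tpass_80_80={len(kept_alns)}"
        )
        report[f"mapped_{name}"] = len(alns)
        report[f"mapped_pass_{name}"] = len(kept_alns)

    pileups: dict[tuple[str, str], object] = {}
    for name, alns in mapped.items():
        for genome_id in sorted(genomes):
            pileups[(name, genome_id)] = build_pileup(
                alns, genome_id, len(genomes[genome_id])
            )

    # ---- stage: dN/dS ------------------------------------------------------
    if config.run_dnds:
        for name in kept_sets:
            records = []
            for genome_id in sorted(genomes):
                genome_genes = [g for g in genes if g.genome == genome_id]
                records.extend(
                    compute_gene_records(
                        pileups[(name, genome_id)],
                        genome_genes,
                        min_depth=config.min_depth,
                        min_variant_count=config.min_variant_count,
                        min_covered_nt=config.min_covered_nt,
                    )
                )
            records = dedupe(records, None)
            with open(outdir / f"dnds_records_{name}.tsv", "w") as fh:
                fh.write(
                    "gene_id\tgene_class\ts_pot\tn_pot\ts_obs\tn_obs\tdnds\t"
                    "mean_depth\tcovered_nt\tincluded\texclusion_reason\n"
                )
                for r in records:
                    val = "NA" if r.dnds is None else f"{r.dnds:.6f}"
                    fh.write(
                        f"{r.gene_id}\t{r.gene_class}\t{r.s_pot:.4f}\t"
                        f"{r.n_pot:.4f}\t{r.s_obs}\t{r.n_obs}\t{val}\t"
                        f"{r.mean_depth:.3f}\t{r.covered_nt_at_min_depth}\t"
                        f"{int(r.included)}\t{r.exclusion_reason}\n"
                    )
            classes = sorted({r.gene_class for r in records if r.gene_class})
            summaries = {}
            for cls in classes or ["all"]:
                cls_records = [
                    r for r in records if (r.gene_class or "all") == cls
                ]
                try:
                    s = summarize(cls_records)
                except ValueError:
                    continue
                summaries[cls] = {
                    "n_genes": s.n_genes,
                    "n_undefined": s.n_undefined,
                    "mean_dnds": round(s.mean_dnds, 6),
                    "ci95_low": round(s.ci95[0], 6),
                    "ci95_high": round(s.ci95[1], 6),
                    "n_genes_purifying": s.n_genes_purifying,
                }
                edges, counts = histogram(cls_records)
                with open(outdir / f"dnds_hist_{name}_{cls}.tsv", "w") as fh:
                    fh.write("bin_low\tbin_high\tcount\n")
                    for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                        fh.write(f"{lo:.1f}\t{hi:.1f}\t{int(c)}\n")
            _json_dump(summaries, outdir / f"dnds_summary_{name}.json")
            report[f"dnds_{name}"] = summaries
            log_lines.append(f"dnds\t{name}\tgenes={len(records)}")

    # ---- stage: enrichment + hit tallies (synthetic annotations) -----------
    if config.run_enrichment and truth is not None:
        import pandas as pd

        profiles = {}
        taxa_by_set = {}
        for name, rs in kept_sets.items():
            rows, taxa = _read_annotations(rs, truth)
            taxa_by_set[name] = taxa
            df = pd.DataFrame(
                rows, columns=["read_id", "category", "evalue", "identity"]
            )
            df.to_csv(outdir / f"annotations_{name}.tsv", sep="\t", index=False)
            profiles[name] = tally_profile(
                df, metagenome_id=name, scheme="SEED", total_reads=len(rs)
            )
        names = sorted(profiles)
        if len(names) == 2:
            results = diff_medians_test(
                profiles[names[0]],
                profiles[names[1]],
                sample_size=config.enrich_sample_size,
                confidence=config.enrich_confidence,
                repetitions=config.enrich_repetitions,
                null_experiments=config.enrich_null_experiments,
                seed=config.seed * 1000 + 7,
            )
            with open(outdir / "enrichment.tsv", "w") as fh:
                fh.write(
                    "category\tmedian_diff\tnull_low\tnull_high\t"
                    "significant\tdirection\n"
                )
                for r in results:
                    fh.write(
                        f"{r.category}\t{r.median_diff:.1f}\t{r.null_ci[0]:.1f}"
                        f"\t{r.null_ci[1]:.1f}\t{int(r.significant)}\t"
                        f"{r.direction}\n"
                    )
            report["enrichment_significant"] = sorted(
                r.category for r in results if r.significant
            )

        tallies = []
        for name, rs in kept_sets.items():
            for kind in ("prophage", "mge"):
                rows = _hit_rows(rs, truth, kind)
                df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
                path = outdir / f"hits_{kind}_{name}.tsv"
                df.to_csv(path, sep="\t", index=False, header=False)
                if len(rs) > 0:
                    tallies.append(
                        tally_unique_hits(
                            df,
                            total_reads=len(rs),
                            metagenome_id=name,
                            query_set=kind,
                        )
                    )
        if tallies:
            table = rank_metagenomes(tallies)
            table.to_csv(outdir / "hit_tally_ranking.tsv", sep="\t", index=False)
            report["hit_percents"] = {
                f"{t.metagenome_id}:{t.query_set}": round(t.percent, 2)
                for t in tallies
            }

    # ---- stage: islands ----------------------------------------------------
    if config.run_islands:
        window = config.island_window
        for genome_id in sorted(genomes):
            key = ("cellular" if "cellular" in mapped else next(iter(mapped)),
                   genome_id)
            pileup = pileups[key]
            raw = pileup.depth.astype(float)
            win = min(window, raw.size)
            track = CoverageTrack(reference_id=genome_id, raw=raw, window=win)
            try:
                found = call_islands(
                    track,
                    rel_threshold=config.island_rel_threshold,
                    min_length=config.island_min_length,
                    genes=[g for g in genes if g.genome == genome_id],
                )
            except ValueError as exc:
                log_lines.append(f"islands\t{genome_id}\tskipped ({exc})")
                continue
            with open(outdir / f"islands_{genome_id}.tsv", "w") as fh:
                fh.write(
                    "start\tend\tmean_smoothed\tgenome_median\t"
                    "flagged_excluded\toverlapping_genes\n"
                )
                for isl in found:
                    fh.write(
                        f"{isl.start}\t{isl.end}\t"
                        f"{isl.mean_smoothed_coverage:.3f}\t"
                        f"{isl.genome_median_coverage:.3f}\t"
                        f"{int(isl.flagged_excluded)}\t"
                        f"{','.join(isl.overlapping_genes)}\n"
                    )
            log_lines.append(f"islands\t{genome_id}\tn={len(found)}")
            report[f"islands_{genome_id}"] = len(found)

    # ---- stage: viral subset ----------------------------------------------
    if config.run_subset and truth is not None and "viral" in kept_sets:
        rs = kept_sets["viral"]
        taxa = taxa_by_set.get("viral", {}) if config.run_enrichment else {}
        bins: dict[str, list[str]] = {}
        lengths: dict[str, int] = {}
        for read in rs.reads:
            b = read.start // config.contig_bin_size
            cid = f"{read.genome}_c{b:05d}"
            bins.setdefault(cid, []).append(read.read_id)
            lengths[cid] = min(
                config.contig_bin_size,
                len(truth.genomes[read.genome]) - b * config.contig_bin_size,
            )
        read_len = {r.read_id: len(r.sequence) for r in rs.reads}
        contigs = []
        for cid in sorted(bins):
            members = bins[cid]
            mean_cov = sum(read_len[m] for m in members) / lengths[cid]
            contigs.append(
                ContigRecord(
                    contig_id=cid,
                    length_nt=lengths[cid],
                    mean_coverage=mean_cov,
                    member_reads=members,
                    majority_taxon=contig_taxonomy(members, taxa),
                )
            )
        kept_ids, tally = viral_subset(
            [r.read_id for r in rs.reads],
            contigs,
            min_coverage=config.subset_min_coverage,
        )
        with open(outdir / "viral_subset_manifest.tsv", "w") as fh:
            fh.write("read_id\n")
            for rid in kept_ids:
                fh.write(rid + "\n")
        log_lines.append(
            f"subset\tviral\tkept={tally['kept']}\tremoved={tally['removed']}\t"
            f"unassembled={tally['unassembled']}"
        )
        report["subset"] = tally

    # ---- provenance and report --------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["outdir"] = "."  # bundle-relative so reruns compare byte-for-byte
    _json_dump({"config": cfg_dict, "version": __version__},
               outdir / "provenance.json")
    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    _json_dump(report, outdir / "report.json")
    return report
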