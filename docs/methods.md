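# Methods

This note documents the models and procedures implemented in `ventpop`,
the parameters that matter, the design choices made where the underlying
description was open, and what the synthetic validation does and does not
demonstrate.

## Population dN/dS from mapped reads

### Model

Metagenomic reads mapped to a reference gene at ≥ 80% identity and ≥ 80%
read coverage are treated as draws from a single environmental
population; the mapped reads define that population. A majority-rule
consensus is called per reference position from the pileup, and
polymorphism relative to the consensus is partitioned into synonymous and
nonsynonymous changes. Potential site counts follow the Nei–Gojobori
convention: for each consensus codon, each position contributes
(synonymous single-base neighbours)/3 synonymous sites, the remainder
nonsynonymous, so every codon contributes exactly 3 sites. The per-gene
statistic is the rate ratio

    pN/pS = (N_obs / N_pot) / (S_obs / S_pot).

Because all sequences come from one population at low divergence, no
multiple-hit (Jukes–Cantor) correction is applied and no claim is made
about which polymorphisms are fixed; the statistic indexes standing
diversification, with values < 1 indicating purifying selection.

### Parameters and rules

| parameter | default | meaning |
|---|---|---|
| `min_identity`, `min_read_coverage` | 0.80 / 0.80 | mapping acceptance rule, inclusive (≥) |
| `min_depth` | 5 | positions below 5X are masked |
| `min_covered_nt` | 100 | genes need ≥ 100 nt at ≥ 5X to be included |
| `min_variant_count` | 2 | a non-consensus base must be seen twice to count |
| CI level | 95% (Student-t) | over the pN/pS < 1 subset of a cohort |

Decisions taken where the procedure was open, all flagged in the API:

* **Consensus ties and sub-threshold depth** mask the position; a codon
  with any masked position is dropped from both the potential and the
  observed tallies, preserving `S_pot + N_pot = 3 × unmasked codons`.
* **Mutations to stop codons count as nonsynonymous** (some
  Nei–Gojobori variants exclude them; counting them keeps the 3-sites-
  per-codon invariant). Stop codons appearing *in* the consensus are
  skipped and tallied as diagnostics.
* **Each distinct variant base counts once per position** regardless of
  read support beyond the threshold; `count_per_read=True` switches to
  read-weighted counting. The default guards against coverage imbalance
  dominating the ratio.
* **`min_variant_count=2`** suppresses single-read sequencing error; at
  the simulated carrier frequencies (≥ 20%) and 30X depth the chance of
  a true variant being seen fewer than twice is small, so the rule costs
  little sensitivity there. On real low-coverage genes it biases both
  counts downward roughly proportionally.
* **Genes with `S_obs = 0` are undefined** and excluded from cohort
  means; their count is reported (`n_undefined`). The alternative —
  division by zero or pseudocounts — would manufacture extreme values.
* **Redundancy** is resolved by keeping the highest-mean-depth member of
  each declared redundancy group (ties to the smallest gene id). What
  counts as "redundant" is supplied by the caller as a gene→group map;
  the pipeline default declares no groups.
* The cohort **CI uses Student-t**; at cohort sizes in the hundreds this
  is indistinguishable from a normal interval.
* Histogram bins are 0.1-wide up to 1 and 0.5-wide beyond, matching the
  conventional presentation of purifying-dominated distributions.

### Estimator bias

The per-gene ratio is a ratio of small counts, so cohort means inherit a
Jensen-type upward bias of order `1/E[S_obs]`. At the validation settings
(999-nt genes, 2% polymorphic sites) this is a few percent to ~15% at the
lowest planted ratios — visible in the recovery numbers, which sit
slightly above the planted values while remaining within the 20%
validation band. Users comparing cohorts should compare like with like
(similar gene length and coverage), as the original analysis does.

## Read QC

Four thresholds applied in fixed order (length, mean quality, N count,
complexity), each read rejected with its first failing rule. The
complexity score is the Shannon entropy of overlapping trinucleotide
frequencies scaled to 0–100 by the maximum attainable at the read's
length (`log2 min(64, L−2)`). The tool originally used for this filter
does not publish its exact entropy formula; this implementation is
documented as chosen, not asserted as identical, and the threshold (70)
keeps its conventional meaning of "reject low-complexity reads" —
homopolymers score 0, dinucleotide repeats ~16, typical genomic sequence
> 90. Mean quality is the arithmetic mean of Phred values (not error
probabilities), the simplest reading of a "mean quality score" threshold.

## Internal mapper

A desk-scale substitute for a production read mapper, adequate for reads
a few percent diverged from the reference: up to 8 evenly spaced exact
15-mers vote for (reference, diagonal) in both orientations; the best
diagonal per orientation is extended with an infix (semi-global) edlib
alignment over a padded window; the lower edit distance wins, ties to
the forward strand then lowest coordinate. Reads without seed hits or
beyond 25% edits are unmapped. Identity is computed over aligned columns
(gaps and clips excluded); read coverage over the full read length
including clips — the strictest common reading of an "80% identity, 80%
coverage" rule; whether the original rule measured read or gene coverage
is not stated, and read coverage is chosen here. Insertions relative to
the reference contribute nothing to pileups, deletions contribute no
base: the downstream statistic is substitution-based.

## Difference-of-medians enrichment test

The observed statistic per category is the median, over `repetitions`
(default 1000) draws, of the difference in category counts between two
subsamples of `sample_size` (default 5000) annotations drawn with
replacement from each profile. The null distribution is built from the
pooled profile as full pseudo-experiments: each of `null_experiments`
(default 200) iterations draws two pseudo-profiles of the original
profile sizes from the pooled category proportions and recomputes the
same median-of-differences statistic. A category is significant when the
observed median falls outside the central 95% interval of the null
statistics.

The original tool is described only by its confidence level and sample
size. The pseudo-experiment null is this package's design: it makes the
null distribution match the sampling distribution of the observed
statistic (both include profile-level and subsample-level noise), which
is what makes the test approximately exact — empirically, the type-I
rate over 500 null profile pairs is ~6% at 95% confidence, and a 2×
planted category at 20%-vs-10% relative abundance is detected with power
1.0. A null built from single pooled draws (without regenerating
pseudo-profiles) is grossly conservative because the median over
repetitions concentrates much faster than a single draw spreads.
Exact antisymmetry under swapping the two profiles is guaranteed by
canonicalising the pair order internally. The calibration experiments
run at `repetitions=150, null_experiments=120`; the statistic's
calibration is insensitive to the inner repetition count, which controls
only the residual subsample noise in the median.

## Unique-hit tallies

For screens against protein collections (prophage proteins,
transposase/integrase/recombinase/resolvase families), a read counts
once regardless of its number of hits at e ≤ 1e-5, and the tally is
normalised to the metagenome's total reads as a percent. Ranking tables
sort descending by exact percent with ties broken by metagenome id;
percents are rounded only at output, to the table's printed precision.

## Coverage, smoothing, islands

Per-base recruitment coverage is accumulated from alignment intervals
(O(N) difference-array). Smoothing is a centred moving average (default
window 50 kb) computed with cumulative sums; edge windows truncate and
divide by the actual overlap, so a constant track is preserved exactly.
GC tracks use the same windowing with N bases excluded from numerator
and denominator.

Islands are maximal runs where smoothed coverage < `rel_threshold`
(default 0.5) × the genome median, at least `min_length` (default 10 kb)
long. The numeric rule is this package's operationalisation — the
phenomenon is classically identified by inspection of recruitment plots,
with islands in the tens of kilobases — and both knobs are exposed. The
genome median is computed outside declared exclusion intervals (e.g.
CRISPR loci, which recruit poorly for reasons unrelated to gene
content), and islands overlapping an exclusion interval are flagged
rather than deleted, leaving the judgement to the analyst. Island calls
are invariant to uniform coverage scaling by construction.

## Contig taxonomy and the viral subset

A contig's taxon is the strict majority (> 50%) of its *annotated*
member reads; ties or no annotations give `unknown`. The
decontamination rule keeps a virome read iff its contig has mean
coverage ≥ 8 (inclusive) or majority taxon in {viral, archaeal_virus,
bacterial_virus, unknown}. Coverage is evaluated per contig mean.
Unassembled reads are retained by default — the rule is stated over
assembled reads — with a switch to drop them. The filter is idempotent,
monotone in the coverage cutoff, and never removes reads from
viral/unknown contigs.

## Synthetic community generator

The generator emulates the data regime the analyses were designed for:

* **Genomes**: multi-genome community, genes of configurable length
  (default validation uses 999 nt) alternating strands, separated by
  intergenic spacers, at a target GC (realized within ±0.02 for ≥100-kb
  genomes). Genes are ATG + random sense codons + stop under translation
  table 11.
* **Population**: each genome has `n_haplotypes` full-length variants.
  Polymorphisms are site-level biallelic variants carried by a minority
  of haplotypes (carrier frequency uniform in [0.20, 0.45]), so the
  majority consensus equals the base genome and variants reach callable
  read support at ~30X. 2% of coding sites are polymorphic by default —
  a plausible within-population diversity under an 80%-identity
  definition of the population. One site per codon at most; start/stop
  codons and intergenic DNA are left invariant; no planted change
  creates an internal stop.
* **Planted dN/dS**: per gene, the number of synonymous vs nonsynonymous
  sites is chosen so the class-level rate ratio equals the class target
  (largest-remainder rounding across genes); each substitution is then a
  concrete single-base change classified by codon table, so an
  independent recount of the truth tables reproduces the target.
* **Reads**: 454-style single-end reads, lengths uniform in 100–300 nt,
  Sanger Phred+33, constant quality except a configurable low-quality
  fraction (QC material). Start positions are weighted so planted
  islands are sampled at `presence_fraction` × the background rate, and
  arbitrary region weights support biased (e.g. provirus-enriched)
  libraries. Optional uniform substitution errors.
* **Truth tables**: genomes FASTA, gene models GFF3 (1-based inclusive),
  reads FASTQ, and plain TSVs for sites, per-gene/per-class realized
  ratios, and feature coordinates. Identical config+seed gives
  byte-identical output.

What the generator does **not** model: 454 homopolymer errors and
flowgrams, assembly (pipeline "contigs" are coordinate bins labelled as
synthetic stand-ins), annotation noise (truth-derived annotation tables
are exact), genome rearrangement, and read-length/quality correlation.
Passing validation therefore demonstrates correctness of the statistical
machinery under the stated population model — not robustness to
platform-specific artefacts, mis-assembly or annotation error in real
data.

## Validation experiment sizes

The packaged experiments (`ventpop.validation`, also run by
`scripts/acceptance.py`) use: cohorts of 100 genes × 999 nt, 20
haplotypes, 30X error-free coverage for single-cohort recovery at
dN/dS ∈ {0.1, 0.5, 1.0} (tolerance: 20% relative); 200 genes per class
for the 0.15-vs-0.22 contrast (requires ordering and disjoint 95% CIs);
500 null profile pairs for type-I calibration (acceptance band 2–8% at
95% confidence) and 20 pairs for 2× power (≥ 0.9); a 40-kb island at
presence 0.2 in a ~1-Mb genome at 20X with a 50-kb window (boundary
error ≤ window/2, and zero islands on a uniform control); and double
runs of the full synthetic pipeline for byte-identical determinism.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GFF3 converts at I/O.
Ambiguous (non-ACGT) read bases never enter pileups. An all-zero
coverage track has no defined median and island calling fails
explicitly. Profiles with zero annotations, zero-read tallies, cohorts
with fewer than two defined ratios, and reads assigned to two contigs
all raise errors rather than returning silent defaults. All randomness
flows through `numpy.random.default_rng` seeds; every experiment and the
pipeline are reproducible byte-for-byte at fixed seed.

## Known limitations

* pN/pS conflates within-population polymorphism with any residual
  between-taxon divergence admitted by the 80% identity rule.
* The ratio-of-counts estimator is biased upward for genes with few
  synonymous events; cohort comparisons are safer than absolute values.
* The internal mapper is not a production aligner: no affine-gap
  scoring, no mapping-quality model, single best hit only.
* The island rule fixes a threshold where the literature uses visual
  inspection; boundary precision is limited to about half the smoothing
  window.
* The enrichment null assumes annotations are independent draws; linked
  annotations (multi-hit reads) would make it anticonservative.
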