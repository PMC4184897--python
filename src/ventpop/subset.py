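"""Contig-level taxonomy and the viral-subset decontamination filter.

Virome sequencing libraries routinely carry cellular contamination.  The
in-silico decontamination rule keeps a read if it was assembled into a
contig with mean coverage of 8 or greater, OR into a contig whose
majority read annotation is viral (any virus taxon) or unknown; reads on
low-coverage contigs with confident cellular (bacterial/archaeal)
annotation are removed as probable contamination.  Reads not assembled
into any contig are retained by default — the rule is stated over
assembled reads — and this is switchable.

A contig's taxon is the strict majority of its annotated member reads;
ties, or contigs without annotated reads, are ``unknown``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TAXA",
    "VIRAL_TAXA",
    "ContigRecord",
    "contig_taxonomy",
    "viral_subset",
]

TAXA = ("archaea", "bacteria", "archaeal_virus", "bacterial_virus", "viral", "unknown")
VIRAL_TAXA = frozenset({"viral", "archaeal_virus", "bacterial_virus"})


@dataclass
class ContigRecord:
    contig_id: str
    length_nt: int
    mean_coverage: float
    member_reads: list[str] = field(default_factory=list)
    majority_taxon: str = "unknown"


def contig_taxonomy(
    member_reads: Sequence[str],
    read_annotations: Mapping[str, str],
) -> str:
    """Strict-majority taxon of a contig's annotated member reads.

    Reads without an annotation are ignored; if no label exceeds half of
    the annotated reads (or none are annotated), the contig is
    ``unknown``.
    """
    labels = [read_annotations[r] for r in member_reads if r in read_annotations]
    labels = [lab for lab in labels if lab]
    if not labels:
        return "unknown"
    counts = Counter(labels)
    top_label, top_count = counts.most_common(1)[0]
    if 2 * top_count > len(labels):
        return top_label
    return "unknown"


def viral_subset(
    read_ids: Iterable[str],
    contigs: Sequence[ContigRecord],
    min_coverage: float = 8.0,
    keep_unassembled: bool = True,
) -> tuple[list[str], dict[str, int]]:
    """Apply the coverage-or-annotation decontamination rule.

    Returns the kept read ids (input order preserved) and a kept/removed
    tally.  A read assembled into more than one contig is an error:
    contig membership must partition the assembled reads.
    """
    membership: dict[str, str] = {}
    keep_contig: dict[str, bool] = {}
    for contig in contigs:
        keep_contig[contig.contig_id] = (
            contig.mean_coverage >= min_coverage
            or contig.majority_taxon in VIRAL_TAXA
            or contig.majority_taxon == "unknown"
        )
        for read_id in contig.member_reads:
            if read_id in membership:
                raise ValueError(
                    f"read {read_id} assigned to contigs {membership[read_id]} "
                    f"and {contig.contig_id}; membership must be a partition"
                )
            membership[read_id] = contig.contig_id

    kept: list[str] = []
    tally = {"kept": 0, "removed": 0, "unassembled": 0}
    for read_id in read_ids:
        contig_id = membership.get(read_id)
        if contig_id is None:
            tally["unassembled"] += 1
            if keep_unassembled:
                kept.append(read_id)
                tally["kept"] += 1
            else:
                tally["removed"] += 1
        elif keep_contig[contig_id]:
            kept.append(read_id)
            tally["kept"] += 1
        else:
            tally["removed"] += 1
    return kept, tally
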