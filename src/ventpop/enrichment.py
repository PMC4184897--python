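"""Functional-category profiles, homology-hit tallies and enrichment tests.

Two kinds of comparison are supported:

* **Unique-hit tallies** (mobile-element / provirus screens): the number
  of distinct reads with at least one homology hit at e <= 1e-5 is
  normalised to the metagenome's read total and reported as a percent, so
  metagenomes of different depth can be ranked.

* **Category enrichment** between two metagenomes: annotation counts per
  functional category (SEED / COG / KO, e <= 1e-3) are compared with a
  nonparametric difference-of-medians resampling test at 95% confidence
  and a subsample size of 5000 annotations.  Each repetition draws
  ``sample_size`` annotations with replacement from each profile and
  records the per-category count difference; the observed statistic is
  the median difference.  The null distribution is built from the pooled
  profile: each null experiment draws two pseudo-profiles of the original
  sizes from the pooled category proportions and computes the same
  median-of-differences statistic, so the null reflects both profile-level
  and subsample-level sampling noise and the test is approximately exact.
  A category is significant when the observed median lies outside the
  central 95% interval of the null statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalProfile",
    "HitTally",
    "EnrichmentResult",
    "tally_profile",
    "tally_unique_hits",
    "rank_metagenomes",
    "diff_medians_test",
    "proportion_percent",
    "export_profile_chart",
]

SCHEMES = ("SEED", "COG", "KO")

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class FunctionalProfile:
    metagenome_id: str
    scheme: str
    counts: dict[str, int]
    total_reads: int
    min_evalue: float = 1e-3
    min_identity: float = 0.6
    n_excluded: int = 0

    @property
    def total_annotations(self) -> int:
        return sum(self.counts.values())


@dataclass
class HitTally:
    metagenome_id: str
    query_set: str
    unique_hit_reads: int
    total_reads: int

    @property
    def percent(self) -> float:
        return 100.0 * self.unique_hit_reads / self.total_reads


@dataclass
class EnrichmentResult:
    category: str
    median_diff: float
    null_ci: tuple[float, float]
    significant: bool
    direction: str  # 'A' | 'B' | 'none'


def tally_profile(
    annotations: str | Path | pd.DataFrame,
    metagenome_id: str,
    scheme: str = "SEED",
    min_evalue: float = 1e-3,
    min_identity: float = 0.6,
    level: int | None = None,
    total_reads: int | None = None,
) -> FunctionalProfile:
    """Tally category abundance counts from an annotation table.

    The table needs columns ``read_id``, ``category``, ``evalue`` and
    ``identity`` (identity as a fraction).  Hierarchical categories use
    ';'-separated paths; ``level`` truncates them to the first ``level``
    components (None keeps the full path).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if isinstance(annotations, (str, Path)):
        df = pd.read_csv(annotations, sep="\t")
    else:
        df = annotations.copy()
    required = {"read_id", "category", "evalue", "identity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    passing = df[(df["evalue"] <= min_evalue) & (df["identity"] >= min_identity)]
    n_excluded = len(df) - len(passing)
    cats = passing["category"].astype(str)
    if level is not None:
        cats = cats.map(lambda c: ";".join(c.split(";")[:level]))
    counts = cats.value_counts().to_dict()
    return FunctionalProfile(
        metagenome_id=metagenome_id,
        scheme=scheme,
        counts={str(k): int(v) for k, v in counts.items()},
        total_reads=int(total_reads if total_reads is not None else df["read_id"].nunique()),
        min_evalue=min_evalue,
        min_identity=min_identity,
        n_excluded=n_excluded,
    )


def tally_unique_hits(
    hits: str | Path | pd.DataFrame,
    total_reads: int,
    metagenome_id: str = "",
    query_set: str = "",
    max_evalue: float = 1e-5,
) -> HitTally:
    """Count distinct reads with a passing hit in a BLAST outfmt-6 table.

    A read counts once no matter how many hits it has; the tally is
    normalised to ``total_reads`` (the metagenome's read count) as a
    percent.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if isinstance(hits, (str, Path)):
        df = pd.read_csv(hits, sep="\t", header=None, names=BLAST6_COLUMNS,
                         comment="#")
    else:
        df = hits
    passing = df[df["evalue"] <= max_evalue]
    unique = int(passing["qseqid"].nunique())
    if unique > total_reads:
        raise ValueError("more unique hit reads than reads in the metagenome")
    return HitTally(
        metagenome_id=metagenome_id,
        query_set=query_set,
        unique_hit_reads=unique,
        total_reads=total_reads,
    )


def proportion_percent(positive: int, total: int, ndigits: int = 0) -> float:
    """Percent of positives in a survey, rounded for report printing."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * positive / total, ndigits)


def rank_metagenomes(tallies: Sequence[HitTally], ndigits: int = 2) -> pd.DataFrame:
    """Ranking table, descending by percent; ties order by metagenome_id."""
    if not tallies:
        raise ValueError("need at least one tally")
    rows = [
        {
            "metagenome_id": t.metagenome_id,
            "query_set": t.query_set,
            "reads": t.total_reads,
            "unique_hit_reads": t.unique_hit_reads,
            "percent": round(t.percent, ndigits),
            "_exact": t.percent,
        }
        for t in tallies
    ]
    df = pd.DataFrame(rows).sort_values(
        by=["_exact", "metagenome_id"], ascending=[False, True], kind="mergesort"
    )
    return df.drop(columns="_exact").reset_index(drop=True)


# ---------------------------------------------------------------------------
# difference-of-medians resampling test
# ---------------------------------------------------------------------------

def _median_diff_stat(
    rng: np.random.Generator,
    p_a: np.ndarray,
    p_b: np.ndarray,
    sample_size: int,
    repetitions: int,
) -> np.ndarray:
    draws_a = rng.multinomial(sample_size, p_a, size=repetitions)
    draws_b = rng.multinomial(sample_size, p_b, size=repetitions)
    return np.median(draws_a - draws_b, axis=0)


def diff_medians_test(
    profile_a: FunctionalProfile,
    profile_b: FunctionalProfile,
    sample_size: int = 5000,
    confidence: float = 0.95,
    repetitions: int = 1000,
    null_experiments: int = 200,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Per-category difference-of-medians enrichment test (A vs B).

    ``median_diff > 0`` with ``direction='A'`` means the category is
    enriched in ``profile_a``.  The result is exactly antisymmetric under
    swapping the two profiles: internally the pair is ordered by
    ``metagenome_id`` so the same seed yields the same resampling stream
    either way.
    """
    n_a = profile_a.total_annotations
    n_b = profile_b.total_annotations
    if n_a == 0 or n_b == 0:
        raise ValueError("both profiles must contain annotations")

    def _key(p: FunctionalProfile):
        return (p.metagenome_id, tuple(sorted(p.counts.items())))

    flipped = False
    first, second = profile_a, profile_b
    if _key(second) < _key(first):
        first, second = second, first
        flipped = True

    categories = sorted(set(first.counts) | set(second.counts))
    c1 = np.array([first.counts.get(c, 0) for c in categories], dtype=float)
    c2 = np.array([second.counts.get(c, 0) for c in categories], dtype=float)
    p1 = c1 / c1.sum()
    p2 = c2 / c2.sum()

    rng = np.random.default_rng(seed)
    observed = _median_diff_stat(rng, p1, p2, sample_size, repetitions)

    pooled = (c1 + c2) / (c1 + c2).sum()
    null_stats = np.empty((null_experiments, len(categories)))
    for e in range(null_experiments):
        pseudo1 = rng.multinomial(int(c1.sum()), pooled).astype(float)
        pseudo2 = rng.multinomial(int(c2.sum()), pooled).astype(float)
        q1 = pseudo1 / pseudo1.sum()
        q2 = pseudo2 / pseudo2.sum()
        null_stats[e] = _median_diff_stat(rng, q1, q2, sample_size, repetitions)

    tail = (1.0 - confidence) / 2.0
    lows = np.quantile(null_stats, tail, axis=0)
    highs = np.quantile(null_stats, 1.0 - tail, axis=0)

    results: list[EnrichmentResult] = []
    for i, cat in enumerate(categories):
        med = float(observed[i])
        lo, hi = float(lows[i]), float(highs[i])
        if flipped:
            med = -med
            lo, hi = -hi, -lo
        significant = med < lo or med > hi
        if not significant:
            direction = "none"
        else:
            direction = "A" if med > 0 else "B"
        results.append(
            EnrichmentResult(
                category=cat,
                median_diff=med,
                null_ci=(lo, hi),
                significant=significant,
                direction=direction,
            )
        )
    return results


def export_profile_chart(
    profile_a: FunctionalProfile,
    profile_b: FunctionalProfile,
    path: str | Path,
    top_n: int = 20,
) -> None:
    """Paired horizontal bar chart of the two profiles' percent composition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    categories = sorted(
        set(profile_a.counts) | set(profile_b.counts),
        key=lambda c: -(profile_a.counts.get(c, 0) + profile_b.counts.get(c, 0)),
    )[:top_n]
    ta = max(1, profile_a.total_annotations)
    tb = max(1, profile_b.total_annotations)
    pa = [100.0 * profile_a.counts.get(c, 0) / ta for c in categories]
    pb = [100.0 * profile_b.counts.get(c, 0) / tb for c in categories]
    y = np.arange(len(categories))
    fig, ax = plt.subplots(figsize=(8, max(3, 0.35 * len(categories))))
    ax.barh(y - 0.2, pa, height=0.4, label=profile_a.metagenome_id)
    ax.barh(y + 0.2, pb, height=0.4, label=profile_b.metagenome_id)
    ax.set_yticks(y)
    ax.set_yticklabels(categories, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("% of annotations")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
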