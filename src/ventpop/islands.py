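"""Fragment-recruitment coverage analysis and genomic-island detection.

Environmental reads recruited to a reference genome give a per-base
coverage profile; chromosomal regions recruiting markedly fewer reads
than the genome background ("metagenomic islands") are candidates for
strain-variable, often horizontally transferred content.  The profile is
smoothed with a centred moving average (default window 50 kb, matching
the recruitment-plot convention), and maximal runs where the smoothed
coverage falls below half the genome median, at least 10 kb long, are
called as islands.  Intervals expected to recruit poorly for unrelated
reasons (e.g. CRISPR loci, which are highly sample-specific) can be
declared as exclusion intervals: they are left out of the genome-median
estimate and islands overlapping them are flagged rather than deleted.

The numeric island rule (0.5 x median, 10 kb) is this package's
operationalisation of what recruitment plots show visually; both knobs
are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "Island",
    "coverage_track",
    "read_coords_tsv",
    "smooth_track",
    "gc_track",
    "call_islands",
]


@dataclass
class CoverageTrack:
    reference_id: str
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    window: int = 50_000


@dataclass
class Island:
    start: int  # 0-based half-open
    end: int
    mean_smoothed_coverage: float
    genome_median_coverage: float
    overlapping_genes: list[str] = field(default_factory=list)
    flagged_excluded: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def coverage_track(
    intervals: Iterable[tuple[int, int]],
    reference_length: int,
) -> np.ndarray:
    """Per-base depth from alignment intervals (0-based half-open)."""
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    for start, end in intervals:
        if start < 0 or end < start:
            raise ValueError(f"negative or inverted interval ({start}, {end})")
        if end > reference_length:
            raise ValueError(f"interval ({start}, {end}) beyond reference end")
        delta[start] += 1
        delta[end] -= 1
    return np.cumsum(delta[:-1])


def read_coords_tsv(path: str | Path) -> list[tuple[int, int]]:
    """Load show-coords-style recruitment intervals (1-based inclusive).

    Expects at least two columns ``ref_start`` and ``ref_end``; extra
    columns (identity etc.) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"ref_start", "ref_end"} <= set(df.columns):
        raise ValueError("coords TSV needs ref_start and ref_end columns")
    return [(int(s) - 1, int(e)) for s, e in zip(df["ref_start"], df["ref_end"])]


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    lo = np.clip(idx - (window - 1) // 2, 0, n)
    hi = np.clip(idx + window // 2 + 1, 0, n)
    return lo, hi


def smooth_track(raw: np.ndarray, window: int = 50_000) -> np.ndarray:
    """Centred moving average; edge windows truncate (divisor = overlap).

    Computed with cumulative sums (O(N) regardless of window size).
    """
    raw = np.asarray(raw, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > raw.size:
        raise ValueError("window larger than the sequence")
    cs = np.concatenate([[0.0], np.cumsum(raw)])
    lo, hi = _window_bounds(raw.size, window)
    return (cs[hi] - cs[lo]) / (hi - lo)


def gc_track(sequence: str, window: int = 50_000) -> np.ndarray:
    """Centred-window GC fraction; N bases excluded from both terms."""
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > seq.size:
        raise ValueError("window larger than the sequence")
    is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(float)
    is_acgt = (
        (seq == ord("A")) | (seq == ord("C")) | (seq == ord("G")) | (seq == ord("T"))
    ).astype(float)
    cs_gc = np.concatenate([[0.0], np.cumsum(is_gc)])
    cs_ok = np.concatenate([[0.0], np.cumsum(is_acgt)])
    lo, hi = _window_bounds(seq.size, window)
    gc = cs_gc[hi] - cs_gc[lo]
    denom = cs_ok[hi] - cs_ok[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, gc / denom, np.nan)
    return out


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def call_islands(
    track: CoverageTrack,
    rel_threshold: float = 0.5,
    min_length: int = 10_000,
    exclusion_intervals: Sequence[tuple[int, int]] = (),
    genes: Sequence | None = None,
) -> list[Island]:
    """Call maximal low-coverage runs as genomic islands.

    A position belongs to an island when the smoothed coverage is below
    ``rel_threshold`` times the genome median (the median is computed
    over positions outside ``exclusion_intervals``); runs shorter than
    ``min_length`` are dropped.  Islands overlapping an exclusion
    interval are returned with ``flagged_excluded=True``.  ``genes`` may
    be any objects with ``start``/``end``/``gene_id`` attributes; those
    overlapping each island are listed.
    """
    smoothed = track.smoothed
    if smoothed is None:
        smoothed = smooth_track(track.raw, track.window)
        track.smoothed = smoothed
    mask = np.ones(smoothed.size, dtype=bool)
    for start, end in exclusion_intervals:
        mask[max(0, start) : min(smoothed.size, end)] = False
    background = smoothed[mask] if mask.any() else smoothed
    median = float(np.median(background))
    if median <= 0.0:
        raise ValueError("genome median coverage is zero; thresholding undefined")

    below = smoothed < rel_threshold * median
    islands: list[Island] = []
    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_length:
            flagged = any(
                _overlaps(i, j, s, e) for s, e in exclusion_intervals
            )
            overlapping = []
            if genes is not None:
                overlapping = [
                    g.gene_id for g in genes if _overlaps(i, j, g.start, g.end)
                ]
            islands.append(
                Island(
                    start=i,
                    end=j,
                    mean_smoothed_coverage=float(smoothed[i:j].mean()),
                    genome_median_coverage=median,
                    overlapping_genes=overlapping,
                    flagged_excluded=flagged,
                )
            )
        i = j
    return islands
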