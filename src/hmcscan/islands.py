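"""SICER-style window-clustering island caller for enrichment sequencing.

The genome is tiled with non-overlapping windows of ``window_w`` bp; each
retained fragment contributes one point (its strand-shifted centre) to one
window. Windows whose count clears a Poisson upper-tail eligibility
threshold are clustered into islands, allowing up to ``gap_g`` bp of
ineligible windows between eligible ones. Islands are then scored against an
input-control library with a Poisson model and filtered by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hmcscan.intervals import ChromSizes, GenomicInterval, IntervalSet

__all__ = [
    "CallerParams",
    "WindowTrack",
    "Island",
    "deduplicate_fragments",
    "count_windows",
    "eligible_threshold",
    "background_rate",
    "form_islands",
    "score_islands_vs_control",
    "call_islands",
]


@dataclass(frozen=True)
class CallerParams:
    """Island-caller parameters.

    Defaults follow common practice for this algorithm family: 100 bp
    windows, 200 bp fragments, 200 bp gap, redundancy threshold 1, window
    eligibility tail probability 0.2, island FDR 0.01, and an effective
    (mappable) genome fraction of 0.74.
    """

    window_w: int = 100
    fragment_size: int = 200
    gap_g: int = 200
    redundancy_r: int = 1
    window_p0: float = 0.2
    fdr_q: float = 0.01
    effective_genome_fraction: float = 0.74

    def __post_init__(self) -> None:
        if self.window_w <= 0:
            raise ValueError("window_w must be positive")
        if self.gap_g % self.window_w != 0:
            raise ValueError("gap_g must be a multiple of window_w")
        if not (0 < self.window_p0 < 1):
            raise ValueError("window_p0 must be in (0, 1)")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")
        if not (0 < self.effective_genome_fraction <= 1):
            raise ValueError("effective_genome_fraction must be in (0, 1]")
        if self.redundancy_r < 1:
            raise ValueError("redundancy_r must be >= 1")


@dataclass
class WindowTrack:
    """Per-chromosome window counts (one integer per tiling window)."""

    chrom: str
    window_w: int
    counts: np.ndarray  # int64, length = ceil(chrom_length / window_w)

    @property
    def n_windows(self) -> int:
        return len(self.counts)


@dataclass
class Island:
    """A candidate enriched region: a gap-tolerant run of eligible windows."""

    span: GenomicInterval
    score: float
    treat_count: int = 0
    ctrl_count: int = 0
    p_value: float = float("nan")
    q_value: float = float("nan")


def deduplicate_fragments(frags: IntervalSet, r: int = 1) -> IntervalSet:
    """Retain at most ``r`` fragments per identical (chrom, start, end, strand)."""
    if r < 1:
        raise ValueError("redundancy threshold must be >= 1")
    kept: List[GenomicInterval] = []
    seen: Counter = Counter()
    for iv in frags.sorted():
        key = (iv.chrom, iv.start, iv.end, iv.strand)
        if seen[key] < r:
            kept.append(iv)
            seen[key] += 1
    return IntervalSet(kept, is_sorted=True)


def count_windows(frags: IntervalSet, params: CallerParams,
                  chrom_sizes: ChromSizes) -> Dict[str, WindowTrack]:
    """Assign each fragment's strand-shifted centre point to a window.

    The point is the read start shifted by ``fragment_size // 2`` in strand
    direction (for unstranded full fragments this is the midpoint). Points
    past the chromosome end are clipped into the last window.
    """
    w = params.window_w
    shift = params.fragment_size // 2
    tracks = {
        c: WindowTrack(c, w, np.zeros(-(-L // w), dtype=np.int64))
        for c, L in chrom_sizes.sizes.items()
    }
    for iv in frags:
        if iv.chrom not in tracks:
            raise ValueError(f"fragment on unknown chromosome {iv.chrom!r}")
        if iv.strand == "-":
            point = (iv.end - 1) - shift
        elif iv.strand == "+":
            point = iv.start + shift
        else:
            point = (iv.start + iv.end) // 2
        point = min(max(point, 0), chrom_sizes[iv.chrom] - 1)
        tracks[iv.chrom].counts[point // w] += 1
    return tracks


def background_rate(n_frags: int, params: CallerParams,
                    chrom_sizes: ChromSizes) -> float:
    """Expected fragment count per window under a uniform background."""
    effective = params.effective_genome_fraction * chrom_sizes.genome_length
    return n_frags * params.window_w / effective


def eligible_threshold(lambda_bg: float, p0: float) -> int:
    """Smallest integer ``l0`` with ``P(X >= l0 | Poisson(lambda_bg)) < p0``."""
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be positive")
    l0 = 1
    while stats.poisson.sf(l0 - 1, lambda_bg) >= p0:
        l0 += 1
    return l0


def form_islands(track: WindowTrack, l0: int, gap_g: int,
                 lambda_bg: float) -> List[Island]:
    """Cluster eligible windows into islands.

    An island is a maximal run of eligible windows in which consecutive
    eligible windows are separated by at most ``gap_g`` bp of ineligible
    windows; its span runs from the first to the last eligible window (gaps
    included). The score sums ``-ln Poisson_pmf(count; lambda_bg)`` over the
    island's eligible windows.
    """
    w = track.window_w
    gap_windows = gap_g // w
    eligible = np.flatnonzero(track.counts >= l0)
    if len(eligible) == 0:
        return []
    islands: List[Island] = []
    run_start = eligible[0]
    prev = eligible[0]
    runs = []
    for idx in eligible[1:]:
        if idx - prev - 1 > gap_windows:
            runs.append((run_start, prev))
            run_start = idx
        prev = idx
    runs.append((run_start, prev))
    for first, last in runs:
        in_run = eligible[(eligible >= first) & (eligible <= last)]
        score = float(
            -stats.poisson.logpmf(track.counts[in_run], lambda_bg).sum()
        )
        islands.append(
            Island(
                span=GenomicInterval(track.chrom, int(first) * w,
                                     (int(last) + 1) * w),
                score=score,
            )
        )
    return islands


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def score_islands_vs_control(
    islands: Sequence[Island],
    treat_tracks: Dict[str, WindowTrack],
    ctrl_tracks: Dict[str, WindowTrack],
    n_treat: int,
    n_ctrl: int,
    params: CallerParams,
    lambda_bg: float,
) -> List[Island]:
    """Poisson-score islands against the input control; BH-adjust.

    The island's expected treatment count is the library-size-scaled control
    count, floored at the background expectation for its span (so islands
    with zero control coverage never get p = 0). Returns every island with
    ``p_value``/``q_value`` filled in; callers filter on ``q_value <
    params.fdr_q``.
    """
    if n_treat <= 0 or n_ctrl <= 0:
        raise ValueError("library sizes must be positive")
    if not islands:
        return []
    scored: List[Island] = []
    for isl in islands:
        w = params.window_w
        lo, hi = isl.span.start // w, isl.span.end // w
        tcount = int(treat_tracks[isl.span.chrom].counts[lo:hi].sum())
        ccount = int(ctrl_tracks[isl.span.chrom].counts[lo:hi].sum())
        lam = max(ccount * n_treat / n_ctrl,
                  lambda_bg * isl.span.length / w)
        p = float(stats.poisson.sf(tcount - 1, lam))
        scored.append(replace(isl, treat_count=tcount, ctrl_count=ccount,
                              p_value=p))
    qvals = bh_adjust([i.p_value for i in scored])
    return [replace(i, q_value=float(q)) for i, q in zip(scored, qvals)]


def call_islands(
    treat: IntervalSet,
    control: IntervalSet,
    chrom_sizes: ChromSizes,
    params: CallerParams = CallerParams(),
) -> List[Island]:
    """Full pipeline: deduplicate, window, cluster, score, FDR-filter.

    Returns the retained islands (``q_value < fdr_q``) ordered by
    (chrom, start).
    """
    treat_d = deduplicate_fragments(treat, params.redundancy_r)
    ctrl_d = deduplicate_fragments(control, params.redundancy_r)
    treat_tracks = count_windows(treat_d, params, chrom_sizes)
    ctrl_tracks = count_windows(ctrl_d, params, chrom_sizes)
    n_treat, n_ctrl = len(treat_d), len(ctrl_d)
    lam_bg = background_rate(n_treat, params, chrom_sizes)
    l0 = eligible_threshold(lam_bg, params.window_p0)
    candidates: List[Island] = []
    for chrom in sorted(treat_tracks):
        candidates.extend(
            form_islands(treat_tracks[chrom], l0, params.gap_g, lam_bg)
        )
    scored = score_islands_vs_control(
        candidates, treat_tracks, ctrl_tracks, n_treat, n_ctrl, params, lam_bg
    )
    retained = [i for i in scored if i.q_value < params.fdr_q]
    retained.sort(key=lambda i: (i.span.chrom, i.span.start))
    return retained
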