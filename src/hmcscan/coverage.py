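"""Intragenic coverage statistics: per-gene fractions, coverage classes,
metagene profiles, and genome-level enrichment summaries.

The central statistic is the fraction of a gene body (full annotated span,
TSS to TTS including introns) overlapped by a sample's merged peak set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from hmcscan.annotation import GeneModel
from hmcscan.intervals import ChromSizes, IntervalSet, merge

__all__ = [
    "COVERAGE_CLASSES",
    "coverage_class",
    "classify_coverage",
    "intragenic_coverage",
    "coverage_matrix",
    "metagene",
    "MetageneProfile",
    "enrichment_summary",
    "group_mean_coverage",
]

# Five-level binning of intragenic coverage: no (0%), low (<20%),
# intermediary (20-50%), high (50-80%), very high (>=80%).
COVERAGE_CLASSES = ("none", "low", "intermediary", "high", "very_high")


def coverage_class(f: float) -> str:
    """Coverage class of a fraction; boundaries are lower-inclusive."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"coverage fraction {f} outside [0, 1]")
    if f == 0.0:
        return "none"
    if f < 0.20:
        return "low"
    if f < 0.50:
        return "intermediary"
    if f < 0.80:
        return "high"
    return "very_high"


def classify_coverage(fractions: pd.DataFrame | pd.Series):
    """Vectorized :func:`coverage_class` preserving the input's shape."""
    return fractions.map(coverage_class)


def _prefix_covered(starts: np.ndarray, ends: np.ndarray,
                    x: np.ndarray) -> np.ndarray:
    """Covered bases strictly before position(s) ``x``.

    ``starts``/``ends`` are a merged (sorted, disjoint) interval list on one
    chromosome.
    """
    x = np.asarray(x, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    k = np.searchsorted(starts, x, side="left")
    covered = cum[k].astype(np.int64)
    pos = k > 0
    if np.any(pos):
        trailing = np.maximum(ends[k[pos] - 1] - x[pos], 0)
        covered[pos] -= trailing
    return covered


def covered_in_ranges(starts: np.ndarray, ends: np.ndarray,
                      lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Covered bases within each half-open range ``[lo_i, hi_i)``."""
    lo = np.asarray(lo, dtype=np.int64)
    hi = np.asarray(hi, dtype=np.int64)
    return _prefix_covered(starts, ends, hi) - _prefix_covered(starts, ends, lo)


def intragenic_coverage(gene: GeneModel, peaks: IntervalSet) -> float:
    """Fraction of the gene body covered by the merged peak set."""
    by_chrom = merge(peaks).by_chrom()
    if gene.chrom not in by_chrom:
        return 0.0
    starts, ends = by_chrom[gene.chrom]
    covered = covered_in_ranges(starts, ends,
                                np.array([gene.span.start]),
                                np.array([gene.span.end]))[0]
    return float(covered) / gene.length


def coverage_matrix(genes: Sequence[GeneModel],
                    peaks_by_sample: Mapping[str, IntervalSet]) -> pd.DataFrame:
    """Genes x samples matrix of intragenic coverage fractions in [0, 1]."""
    data = {}
    for sample, peaks in peaks_by_sample.items():
        by_chrom = merge(peaks).by_chrom()
        col = np.zeros(len(genes))
        for i, g in enumerate(genes):
            if g.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[g.chrom]
            covered = covered_in_ranges(
                starts, ends, np.array([g.span.start]), np.array([g.span.end])
            )[0]
            col[i] = covered / g.length
        data[sample] = col
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


@dataclass
class MetageneProfile:
    """Mean covered fraction per bin over a gene set, oriented 5' -> 3'."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self) -> pd.DataFrame:
        labels = (
            [f"up_{i + 1}" for i in range(len(self.upstream))]
            + [f"body_{i + 1}" for i in range(len(self.body))]
            + [f"down_{i + 1}" for i in range(len(self.downstream))]
        )
        zone = (
            ["upstream"] * len(self.upstream)
            + ["body"] * len(self.body)
            + ["downstream"] * len(self.downstream)
        )
        return pd.DataFrame({"bin": labels, "zone": zone, "value": self.values})


def _gene_bin_fractions(gene: GeneModel, starts: np.ndarray, ends: np.ndarray,
                        flank_bp: int, body_bins: int, flank_bins: int,
                        chrom_length: int | None) -> np.ndarray:
    """Per-bin covered fractions for one gene, oriented 5' -> 3'.

    Flank bins truncated at chromosome boundaries use their actual width as
    denominator; zero-width bins yield NaN (excluded from averaging).
    """
    s, e = gene.span.start, gene.span.end
    # genomic bin edges: upstream flank, body (proportional), downstream flank
    up_edges = np.linspace(s - flank_bp, s, flank_bins + 1)
    body_edges = np.linspace(s, e, body_bins + 1)
    down_edges = np.linspace(e, e + flank_bp, flank_bins + 1)
    edges = np.concatenate([up_edges, body_edges[1:], down_edges[1:]])
    lo = np.floor(edges[:-1]).astype(np.int64)
    hi = np.floor(edges[1:]).astype(np.int64)
    # clip at chromosome boundaries
    max_pos = chrom_length if chrom_length is not None else np.iinfo(np.int64).max
    lo_c = np.clip(lo, 0, max_pos)
    hi_c = np.clip(hi, 0, max_pos)
    widths = (hi_c - lo_c).astype(float)
    covered = covered_in_ranges(starts, ends, lo_c, np.maximum(hi_c, lo_c))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(widths > 0, covered / widths, np.nan)
    if gene.span.strand == "-":
        frac = frac[::-1]
    return frac


def metagene(genes: Sequence[GeneModel], peaks: IntervalSet,
             flank_bp: int = 2500, body_bins: int = 40, flank_bins: int = 25,
             chrom_sizes: ChromSizes | None = None) -> MetageneProfile:
    """Average per-bin covered fraction around and within gene bodies.

    The body is length-scaled to ``body_bins`` bins; each flank is
    ``flank_bins`` fixed-width bins covering ``flank_bp`` bp. Minus-strand
    gene profiles are reversed before averaging, so the output always reads
    5' -> 3'.
    """
    by_chrom = merge(peaks).by_chrom()
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    n_bins = 2 * flank_bins + body_bins
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    n_genes = 0
    for g in genes:
        starts, ends = by_chrom.get(g.chrom, empty)
        L = chrom_sizes[g.chrom] if chrom_sizes is not None and g.chrom in chrom_sizes else None
        frac = _gene_bin_fractions(g, starts, ends, flank_bp, body_bins,
                                   flank_bins, L)
        ok = ~np.isnan(frac)
        acc[ok] += frac[ok]
        cnt[ok] += 1
        n_genes += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, 0.0)
    return MetageneProfile(
        upstream=mean[:flank_bins],
        body=mean[flank_bins:flank_bins + body_bins],
        downstream=mean[flank_bins + body_bins:],
        n_genes=n_genes,
    )


def gene_body_profiles(genes: Sequence[GeneModel], peaks: IntervalSet,
                       body_bins: int = 40) -> pd.DataFrame:
    """Per-gene body-bin covered fractions (genes x bins), oriented 5' -> 3'.

    The input to enrichment-pattern clustering: each gene body is
    length-scaled to ``body_bins`` bins with no flanks.
    """
    by_chrom = merge(peaks).by_chrom()
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    rows = np.zeros((len(genes), body_bins))
    for i, g in enumerate(genes):
        starts, ends = by_chrom.get(g.chrom, empty)
        edges = np.linspace(g.span.start, g.span.end, body_bins + 1)
        lo = np.floor(edges[:-1]).astype(np.int64)
        hi = np.floor(edges[1:]).astype(np.int64)
        widths = (hi - lo).astype(float)
        covered = covered_in_ranges(starts, ends, lo, np.maximum(hi, lo))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(widths > 0, covered / widths, 0.0)
        if g.span.strand == "-":
            frac = frac[::-1]
        rows[i] = frac
    return pd.DataFrame(rows, index=[g.gene_id for g in genes],
                        columns=[f"body_{b + 1}" for b in range(body_bins)])


def enrichment_summary(peaks: IntervalSet, genes: Sequence[GeneModel],
                       chrom_sizes: ChromSizes) -> Dict:
    """Genome-level enrichment statistics for one sample's peak set.

    Per chromosome, intragenic space is the merged union of gene spans and
    intergenic space its complement; percentages are covered bp over space
    bp x 100. Peak-length statistics come from the unmerged input peaks.
    """
    merged = merge(peaks)
    peak_lengths = np.array([iv.length for iv in peaks.intervals])
    gene_space = merge(
        IntervalSet([g.span for g in genes])
    ).by_chrom()
    peaks_by_chrom = merged.by_chrom()
    per_chrom: List[Dict] = []
    for chrom, length in chrom_sizes.sizes.items():
        gs, ge = gene_space.get(
            chrom, (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        )
        intragenic_bp = int((ge - gs).sum())
        intergenic_bp = length - intragenic_bp
        ps, pe = peaks_by_chrom.get(
            chrom, (np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        )
        peak_bp = int((pe - ps).sum())
        genic_cov = int(
            covered_in_ranges(ps, pe, gs, ge).sum()
        ) if len(ps) and len(gs) else 0
        inter_cov = peak_bp - genic_cov
        per_chrom.append({
            "chrom": chrom,
            "intragenic_bp": intragenic_bp,
            "intergenic_bp": intergenic_bp,
            "intragenic_covered_bp": genic_cov,
            "intergenic_covered_bp": inter_cov,
            "intragenic_pct": 100.0 * genic_cov / intragenic_bp if intragenic_bp else 0.0,
            "intergenic_pct": 100.0 * inter_cov / intergenic_bp if intergenic_bp else 0.0,
        })
    total_bp = merged.total_length
    hist_edges = np.arange(0, 3200, 200)
    hist, _ = (np.histogram(peak_lengths, bins=hist_edges)
               if len(peak_lengths) else (np.zeros(len(hist_edges) - 1, dtype=int), None))
    return {
        "total_enriched_bp": total_bp,
        "pct_genome_enriched": 100.0 * total_bp / chrom_sizes.genome_length,
        "per_chromosome": pd.DataFrame(per_chrom),
        "peak_length_mean": float(peak_lengths.mean()) if len(peak_lengths) else 0.0,
        "peak_length_median": float(np.median(peak_lengths)) if len(peak_lengths) else 0.0,
        "peak_length_hist": hist,
        "n_peaks": len(peak_lengths),
    }


def group_mean_coverage(coverage: pd.DataFrame,
                        grouping: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Mean coverage per (label, sample), plus group sizes.

    ``grouping`` maps gene_id -> label; genes without a label fall into
    "other".
    """
    gmap = dict(grouping) if not isinstance(grouping, dict) else grouping
    labels = pd.Series([gmap.get(g, "other") for g in coverage.index],
                       index=coverage.index)
    means = coverage.groupby(labels).mean()
    means.insert(0, "n_genes", coverage.groupby(labels).size())
    return means
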