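"""Genomic interval primitives: BED I/O, merging, and overlap arithmetic.

All coordinates are 0-based half-open throughout the package; GTF input is
converted on read (see :mod:`hmcscan.annotation`), BED is native.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Set, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "ChromSizes",
    "merge",
    "overlap_length",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``is_sorted``/``is_merged`` are bookkeeping flags: a merged set is sorted
    by ``(chrom, start)`` and pairwise disjoint, so its total length is the
    number of covered bases.
    """

    intervals: List[GenomicInterval] = field(default_factory=list)
    is_sorted: bool = False
    is_merged: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def sorted(self) -> "IntervalSet":
        if self.is_sorted:
            return self
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, is_sorted=True, is_merged=self.is_merged)

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Merged per-chromosome (starts, ends) int64 arrays.

        The arrays come from ``merge(self)``, so per chromosome they are
        sorted and pairwise disjoint — the representation the coverage
        routines consume.
        """
        merged = merge(self)
        out: Dict[str, List[List[int]]] = {}
        for iv in merged:
            out.setdefault(iv.chrom, [[], []])
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def restrict(self, chrom: str) -> "IntervalSet":
        return IntervalSet(
            [iv for iv in self.intervals if iv.chrom == chrom],
            is_sorted=self.is_sorted,
            is_merged=self.is_merged,
        )


@dataclass
class ChromSizes:
    """Chromosome name -> length map, with the sex-chromosome labels."""

    sizes: Dict[str, int]
    sex_chroms: Set[str] = field(default_factory=lambda: {"chrX", "chrY"})

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    @property
    def genome_length(self) -> int:
        return sum(self.sizes.values())

    @property
    def autosomes(self) -> List[str]:
        return [c for c in self.sizes if c not in self.sex_chroms]

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        for iv in intervals:
            if iv.chrom not in self.sizes:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")


def merge(intervals: IntervalSet) -> IntervalSet:
    """Union of the input intervals (strand-blind).

    Abutting intervals merge (half-open convention: ``[0,10)`` + ``[10,20)``
    -> ``[0,20)``). Idempotent; the result's total length never exceeds the
    input's summed lengths.
    """
    if intervals.is_merged:
        return intervals
    ivs = sorted(intervals.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: List[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end, strand=".")
        else:
            out.append(replace(iv, strand="."))
    return IntervalSet(out, is_sorted=True, is_merged=True)


def overlap_length(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases in the intersection of ``merge(a)`` and ``merge(b)``."""
    am, bm = merge(a).by_chrom(), merge(b).by_chrom()
    total = 0
    for chrom, (sa, ea) in am.items():
        if chrom not in bm:
            continue
        sb, eb = bm[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return total


def read_bed(path: str | Path, chrom_sizes: ChromSizes | None = None) -> IntervalSet:
    """Read a BED3/BED6 file into a sorted :class:`IntervalSet`.

    Lines must have >= 3 whitespace-delimited columns; column 6, when
    present, is parsed as the strand. Malformed lines (non-integer
    coordinates, ``start >= end``) are collected and reported together with
    their line numbers in a single :class:`ValueError`. When ``chrom_sizes``
    is given, an interval on an unlisted chromosome is an error naming it.
    """
    path = Path(path)
    intervals: List[GenomicInterval] = []
    bad: List[Tuple[int, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                bad.append((lineno, "fewer than 3 columns"))
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                bad.append((lineno, "non-integer coordinates"))
                continue
            if start < 0 or start >= end:
                bad.append((lineno, f"invalid span {start}-{end}"))
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValueError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}"
                )
            intervals.append(GenomicInterval(chrom, start, end, strand))
    if bad:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad[:10])
        raise ValueError(f"{path}: {len(bad)} malformed line(s): {detail}")
    return IntervalSet(intervals).sorted()


def write_bed(intervals: IntervalSet, path: str | Path, names: List[str] | None = None,
              scores: List[float] | None = None) -> None:
    """Write BED3 (or BED6 when names/scores given, strand from the interval)."""
    path = Path(path)
    with path.open("w") as fh:
        for k, iv in enumerate(intervals):
            if names is None and scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[k] if names is not None else f"region_{k + 1}"
                score = scores[k] if scores is not None else 0.0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:.6g}\t{iv.strand}\n"
                )


def read_chrom_sizes(path: str | Path,
                     sex_chroms: Iterable[str] = ("chrX", "chrY")) -> ChromSizes:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: Dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(sizes, sex_chroms=set(sex_chroms))
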