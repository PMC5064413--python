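"""Genomic-interval data model, BED/GTF readers and the interval algebra.

All coordinates are 0-based half-open ([start, end)), the BED convention.
GTF input (1-based closed) is converted on read.  Two intervals overlap when
they share at least one base: ``a.start < b.end and b.start < a.end``.
Abutting intervals ([0,5) and [5,9)) are considered contiguous and merge.
Chromosome names are matched verbatim; no "chr" aliasing is applied unless
``normalize_chrom`` is requested by the caller.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class BedParseError(ValueError):
    """Raised for a malformed BED/GTF line; message names the line number."""


class UndefinedInputError(ValueError):
    """Raised when an operation is undefined for the given input (e.g. empty set)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with a strand-dependent transcription start site (TSS)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: require start < end")

    @property
    def tss(self) -> int:
        """5' boundary: start on '+', end on '-'."""
        return self.start if self.strand == "+" else self.end


class RegionSet:
    """An immutable, sorted collection of intervals for one regulator.

    ``merged=True`` guarantees no two intervals on the same chromosome overlap
    or abut.  Sorted order is (chrom, start, end).
    """

    __slots__ = ("regulator", "intervals", "merged", "_index")

    def __init__(
        self,
        regulator: str,
        intervals: Iterable[GenomicInterval],
        merged: bool = False,
        _presorted: bool = False,
    ) -> None:
        self.regulator = regulator
        ivs = list(intervals)
        if not _presorted:
            ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.merged = merged
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionSet)
            and self.regulator == other.regulator
            and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"RegionSet({self.regulator!r}, n={len(self)}, merged={self.merged})"

    def total_bases(self) -> int:
        """Number of distinct bases covered (counts merged coverage)."""
        m = self if self.merged else merge(self)
        return sum(len(iv) for iv in m)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def _merged_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends) arrays of the merged cover, for fast queries."""
        if self._index is None:
            m = self if self.merged else merge(self)
            idx: dict[str, list[list[int]]] = {}
            for iv in m:
                idx.setdefault(iv.chrom, [[], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) on chrom shares >=1 base with this set."""
        idx = self._merged_index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        # merged cover: starts and ends are both strictly increasing, so the
        # only candidate is the last interval starting before `end`.
        i = int(np.searchsorted(starts, end, side="left"))
        return bool(i > 0 and ends[i - 1] > start)


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path: str | Path, regulator: str | None = None) -> RegionSet:
    """Read a BED3/BED6 file into a RegionSet (sorted, merged=False).

    Coordinates are taken verbatim (BED is already 0-based half-open).
    Malformed lines (non-integer coordinates, start >= end, <3 columns)
    raise :class:`BedParseError` naming the offending line number.
    """
    path = Path(path)
    name = regulator if regulator is not None else path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            iv_name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, iv_name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(name, intervals, merged=False)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as sorted BED (3, 4 or 5 columns as data allows)."""
    with open(path, "w") as fh:
        for iv in rs.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_genes(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (feature == "gene") or BED12/BED6.

    GTF 1-based closed coordinates are converted to 0-based half-open
    (start-1, end).  BED coordinates are taken verbatim.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if format == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise BedParseError(f"{path}:{lineno}: expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
                if strand not in ("+", "-"):
                    raise BedParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                gene_id = attrs.get("gene_id")
                if gene_id is None:
                    raise BedParseError(f"{path}:{lineno}: missing gene_id attribute")
                symbol = attrs.get("gene_name", gene_id)
                try:
                    genes.append(
                        GeneModel(gene_id, symbol, chrom, int(start1) - 1, int(end1), strand)
                    )
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    elif format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise BedParseError(f"{path}:{lineno}: expected >=6 BED columns")
                chrom, start, end, name, _, strand = fields[:6]
                if strand not in ("+", "-"):
                    raise BedParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                try:
                    genes.append(GeneModel(name, name, chrom, int(start), int(end), strand))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise ValueError(f"unrecognized gene format {format!r}")
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Interval algebra


def merge(rs: RegionSet) -> RegionSet:
    """Union overlapping or abutting intervals; covers exactly the same bases."""
    out: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in rs.intervals:  # already sorted
        if iv.chrom != cur_chrom:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        elif iv.start <= cur_end:  # overlap or abut
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return RegionSet(rs.regulator, out, merged=True, _presorted=True)


def overlap_fraction(a: RegionSet, b: RegionSet, mode: str = "regions") -> float:
    """Fraction of `a` overlapping `b`; asymmetric by design.

    mode="regions" (default): fraction of intervals of `a` having >=1 bp
    intersection with any interval of `b` — the ranking statistic used to
    order transcription factors by their overlap with each cofactor set.
    mode="jaccard": shared bases / union bases (symmetric alternative).
    """
    if len(a) == 0:
        raise UndefinedInputError("overlap_fraction undefined for empty query set")
    if mode == "regions":
        hit = sum(1 for iv in a if b.overlaps_interval(iv.chrom, iv.start, iv.end))
        return hit / len(a)
    if mode == "jaccard":
        inter = intersect_all([a, b]).total_bases()
        union = merge(RegionSet("u", list(a) + list(b))).total_bases()
        return inter / union if union else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def _intersect_two(a: RegionSet, b: RegionSet) -> list[GenomicInterval]:
    """Base-level intersection of two merged sets (two-pointer sweep)."""
    out: list[GenomicInterval] = []
    by_chrom_a: dict[str, list[GenomicInterval]] = {}
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        by_chrom_a.setdefault(iv.chrom, []).append(iv)
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for chrom in by_chrom_a:
        if chrom not in by_chrom_b:
            continue
        xs, ys = by_chrom_a[chrom], by_chrom_b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def intersect_all(sets: Sequence[RegionSet]) -> RegionSet:
    """Maximal intervals covered by every input set (base-level intersection)."""
    if len(sets) < 2:
        raise ValueError("intersect_all requires >=2 region sets")
    acc = merge(sets[0])
    for other in sets[1:]:
        ivs = _intersect_two(acc, merge(other))
        acc = RegionSet("intersection", ivs, merged=True)
        if len(acc) == 0:
            break
    name = "_".join(s.regulator for s in sets)
    return RegionSet(name, acc.intervals, merged=True, _presorted=True)
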