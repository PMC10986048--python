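"""Genome layouts, half-open regions and the interval algebra used by every scan.

Coordinate convention: everything in memory and in BED output is 0-based,
half-open.  VCF positions are 1-based and converted on read (see
:mod:`admixscan.vcf`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(x <= 0 for x in lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(d.values()))

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths)

    def items(self) -> Iterator[tuple[str, int]]:
        return zip(self.chrom_names, self.chrom_lengths)


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval with a free-text provenance tag."""

    chrom: str
    start: int
    end: int
    tag: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _sort_key(r: Region) -> tuple[str, int, int]:
    return (r.chrom, r.start, r.end)


class RegionSet:
    """A sorted collection of regions supporting merge/intersect/coverage.

    The constructor keeps the regions as given (sorted); :meth:`merge`
    produces a non-overlapping set.  Coverage queries merge internally so
    overlapping members never double-count.
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self.regions: tuple[Region, ...] = tuple(sorted(regions, key=_sort_key))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet(n={len(self)}, bp={self.covered_bp})"

    @property
    def chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return tuple(seen)

    def for_chrom(self, chrom: str) -> "RegionSet":
        return RegionSet(r for r in self.regions if r.chrom == chrom)

    def retag(self, tag: str) -> "RegionSet":
        return RegionSet(replace(r, tag=tag) for r in self.regions)

    def merge(self, max_gap: int = 0) -> "RegionSet":
        return merge_regions(self.regions, max_gap=max_gap)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        return intersect_regions(self, other)

    @property
    def covered_bp(self) -> int:
        return sum(r.length for r in self.merge(0))

    def overlap_bp(self, other: "RegionSet") -> int:
        return self.intersect(other).covered_bp

    def contains_point(self, chrom: str, pos: int) -> bool:
        return any(r.chrom == chrom and r.start <= pos < r.end for r in self.regions)

    # ------------------------------------------------------------------ BED
    @classmethod
    def from_bed(cls, path: str | Path, tag: str = "") -> "RegionSet":
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                name = parts[3] if len(parts) > 3 else tag
                regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
        return cls(regions)

    def to_bed(self, path: str | Path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            for r in self.regions:
                fields = [r.chrom, str(r.start), str(r.end)]
                if r.tag:
                    fields.append(r.tag)
                fh.write("\t".join(fields) + "\n")


def merge_regions(regions: Iterable[Region], max_gap: int = 0) -> RegionSet:
    """Merge regions whose gap is <= ``max_gap`` bp (0 merges book-ended ones).

    Tags of merged constituents are joined (unique, in input-sorted order).
    """
    out: list[Region] = []
    for r in sorted(regions, key=_sort_key):
        if out and r.chrom == out[-1].chrom and r.start - out[-1].end <= max_gap:
            last = out[-1]
            tags = [t for t in (last.tag, r.tag) if t]
            tag = ",".join(dict.fromkeys(",".join(tags).split(","))) if tags else ""
            out[-1] = Region(r.chrom, last.start, max(last.end, r.end), tag)
        else:
            out.append(r)
    return RegionSet(out)


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Exact interval intersection of two region sets (merged internally)."""
    out: list[Region] = []
    am = a.merge(0)
    bm = b.merge(0)
    for chrom in am.chroms:
        xs = [r for r in am if r.chrom == chrom]
        ys = [r for r in bm if r.chrom == chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                tags = [t for t in (xs[i].tag, ys[j].tag) if t]
                tag = ",".join(dict.fromkeys(tags)) if tags else ""
                out.append(Region(chrom, lo, hi, tag))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return RegionSet(out)


def genome_fraction(r: RegionSet, layout: GenomeLayout) -> float:
    """Fraction of the genome covered by ``r`` (regions must fit the layout)."""
    for reg in r:
        if reg.end > layout.length_of(reg.chrom):
            raise ValueError(
                f"region {reg.chrom}:{reg.start}-{reg.end} extends past "
                f"chromosome end {layout.length_of(reg.chrom)}"
            )
    return r.covered_bp / layout.total_bp


def make_windows(layout: GenomeLayout, size: int, step: int | None = None) -> list[Region]:
    """Tile every chromosome with ``size``-bp windows advanced by ``step`` bp.

    Windows are anchored at 0.  Full-length windows are emitted while they
    fit; if the last full window stops short of the chromosome end, one
    truncated terminal window is appended (a chromosome shorter than ``size``
    yields that single truncated window).  ``step == size`` therefore gives a
    non-overlapping tiling that covers the chromosome exactly.
    """
    if step is None:
        step = size
    if size <= 0:
        raise ValueError("window size must be positive")
    if not (0 < step <= size):
        raise ValueError("need 0 < step <= size")
    windows: list[Region] = []
    for chrom, length in layout.items():
        start = 0
        last_end = 0
        while start + size <= length:
            windows.append(Region(chrom, start, start + size))
            last_end = start + size
            start += step
        if last_end < length:
            # terminal truncated window (whole chromosome if shorter than size)
            windows.append(Region(chrom, min(start, last_end), length))
    return windows
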