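"""Target-region geometry for a capture panel.

Regions are exon-level capture targets carried as BED-style 0-based half-open
intervals internally.  Per-base depth files and VCF positions are 1-based;
the converters here are the single place that translation happens.

A base at 1-based position p lies inside region [start, end) iff
start < p <= end, i.e. ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One exon-level target: 0-based half-open [start, end) on chrom.

    exon_index is 1-based within the gene (1 = first exon); splice padding,
    when requested, extends the exon by 2 nt on each side.
    """

    chrom: str
    start: int
    end: int
    gene: str = ""
    exon_index: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self) -> range:
        """All 1-based positions covered by this region."""
        return range(self.start + 1, self.end + 1)

    def contains_pos(self, pos: int) -> bool:
        """True if the 1-based position pos falls inside the region."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class SegDupRegion:
    """A segmental-duplication interval; variants/loci inside one cannot be
    confirmed by unique-locus PCR + Sanger unless the locus was specifically
    validated to amplify unambiguously."""

    chrom: str
    start: int
    end: int
    validated_unambiguous: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")


SPLICE_PAD_NT = 2


def pad_splice(region: TargetRegion, pad: int = SPLICE_PAD_NT) -> TargetRegion:
    """Extend an exon by `pad` nt each side to include splice positions."""
    return TargetRegion(region.chrom, max(0, region.start - pad),
                        region.end + pad, region.gene, region.exon_index)


class RegionIndex:
    """Point/interval lookup over a set of regions (per-chromosome trees)."""

    def __init__(self, regions: Iterable[TargetRegion | SegDupRegion] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._regions: list = []
        for r in regions:
            self.add(r)

    def add(self, region) -> None:
        self._regions.append(region)
        self._trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region)

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator:
        return iter(sorted(self._regions, key=lambda r: (r.chrom, r.start, r.end)))

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(chrom)
        return bool(tree and tree.overlaps_point(pos - 1))

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """Regions overlapping 0-based half-open [start, end)."""
        tree = self._trees.get(chrom)
        if not tree:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]

    def total_bases(self) -> int:
        return sum(r.end - r.start for r in self._regions)
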