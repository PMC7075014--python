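"""Genomic interval algebra on 0-based half-open coordinates.

Every overlap, exclusivity and windowing computation in the pipeline goes
through this module.  The co-location criterion everywhere is *any overlap*
(>= 1 bp); bookended intervals (a.end == b.start) do not overlap, matching
``bedtools intersect`` set semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass
class GenomeInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``attrs`` carries dialect-specific extras (narrowPeak signal/p/q/summit
    columns and the like) so they survive a read/write round trip.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: Optional[float] = None
    strand: str = "."
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and not np.isfinite(self.score):
            raise ValueError("score must be finite")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp (lengths > 0)."""

    def __init__(self, mapping: Mapping[str, int] | Iterable[Tuple[str, int]] = ()):
        super().__init__()
        items = mapping.items() if isinstance(mapping, Mapping) else mapping
        for name, length in items:
            self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if not name:
            raise ValueError("chromosome name must be non-empty")
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, length)

    @property
    def total_length(self) -> int:
        return sum(self.values())


def _sorted_records(intervals: Iterable[GenomeInterval]) -> Dict[str, List[GenomeInterval]]:
    by_chrom: Dict[str, List[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda iv: (iv.start, iv.end, iv.name))
    return dict(sorted(by_chrom.items()))


class IntervalSet:
    """Intervals grouped per chromosome, sorted by (start, end, name).

    A *flattened* set (output of :meth:`merge`) additionally has no
    overlapping or bookended members per chromosome.
    """

    def __init__(self, intervals: Iterable[GenomeInterval] = ()):
        self._by_chrom = _sorted_records(intervals)

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[GenomeInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [iv.key() for iv in self] == [iv.key() for iv in other]

    @property
    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    def on(self, chrom: str) -> List[GenomeInterval]:
        return self._by_chrom.get(chrom, [])

    def to_list(self) -> List[GenomeInterval]:
        return list(self)

    def total_bases(self) -> int:
        """Base count of the flattened union of the set."""
        return sum(len(iv) for iv in self.merge())

    # -- bounds arrays ------------------------------------------------------
    def _bounds(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        ivs = self.on(chrom)
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
        return starts, ends

    # -- algebra ------------------------------------------------------------
    def merge(self, max_gap: int = 0) -> "IntervalSet":
        """Union intervals that overlap or lie within ``max_gap`` bp.

        Bookended intervals (gap 0) merge at ``max_gap=0``.  The result is
        flattened: sorted, disjoint, non-bookended.
        """
        if max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        merged: List[GenomeInterval] = []
        for chrom, ivs in self._by_chrom.items():
            cur_start = cur_end = None
            for iv in ivs:
                if cur_end is None:
                    cur_start, cur_end = iv.start, iv.end
                elif iv.start - cur_end <= max_gap:
                    cur_end = max(cur_end, iv.end)
                else:
                    merged.append(GenomeInterval(chrom, cur_start, cur_end))
                    cur_start, cur_end = iv.start, iv.end
            if cur_end is not None:
                merged.append(GenomeInterval(chrom, cur_start, cur_end))
        return IntervalSet(merged)

    def _overlap_mask(self, other: "IntervalSet") -> Dict[str, np.ndarray]:
        """Per chromosome, boolean mask over self's records: overlaps other?"""
        masks: Dict[str, np.ndarray] = {}
        flat = other.merge()
        for chrom, ivs in self._by_chrom.items():
            starts, ends = self._bounds(chrom)
            b_starts, b_ends = flat._bounds(chrom)
            if len(b_starts) == 0:
                masks[chrom] = np.zeros(len(ivs), dtype=bool)
                continue
            # first flat b-interval whose end > a.start; overlap iff its start < a.end
            j = np.searchsorted(b_ends, starts, side="right")
            mask = np.zeros(len(ivs), dtype=bool)
            inb = j < len(b_starts)
            mask[inb] = b_starts[j[inb]] < ends[inb]
            masks[chrom] = mask
        return masks

    def overlapping(self, other: "IntervalSet") -> "IntervalSet":
        """Subset of self with >= 1 bp overlap in ``other`` (no duplicates)."""
        masks = self._overlap_mask(other)
        return IntervalSet(
            iv
            for chrom, ivs in self._by_chrom.items()
            for iv, keep in zip(ivs, masks[chrom])
            if keep
        )

    def exclusive(self, other: "IntervalSet") -> "IntervalSet":
        """Subset of self with zero overlap in ``other``."""
        masks = self._overlap_mask(other)
        return IntervalSet(
            iv
            for chrom, ivs in self._by_chrom.items()
            for iv, keep in zip(ivs, masks[chrom])
            if not keep
        )

    def extend_clip(self, flank: int, sizes: ChromSizes) -> "IntervalSet":
        """Extend every interval by ``flank`` bp both sides, clipped to the genome.

        Record identity and count are preserved (the result is NOT flattened),
        so downstream gene linking can attribute hits to the original region.
        """
        if flank < 0:
            raise ValueError("flank must be >= 0")
        out = []
        for iv in self:
            if iv.chrom not in sizes:
                raise KeyError(f"chromosome {iv.chrom!r} absent from sizes")
            length = sizes[iv.chrom]
            out.append(
                GenomeInterval(
                    iv.chrom,
                    max(0, iv.start - flank),
                    min(length, iv.end + flank),
                    name=iv.name,
                    score=iv.score,
                    strand=iv.strand,
                    attrs=dict(iv.attrs),
                )
            )
        return IntervalSet(out)

    def intersect_bases(self, other: "IntervalSet") -> int:
        """Number of bases covered by both flattened sets."""
        shared = 0
        a, b = self.merge(), other.merge()
        for chrom in a.chroms:
            a_starts, a_ends = a._bounds(chrom)
            b_starts, b_ends = b._bounds(chrom)
            i = j = 0
            while i < len(a_starts) and j < len(b_starts):
                lo = max(a_starts[i], b_starts[j])
                hi = min(a_ends[i], b_ends[j])
                if hi > lo:
                    shared += int(hi - lo)
                if a_ends[i] <= b_ends[j]:
                    i += 1
                else:
                    j += 1
        return shared

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Flattened per-base difference self \\ other."""
        a, b = self.merge(), other.merge()
        out: List[GenomeInterval] = []
        for chrom in a.chroms:
            b_ivs = b.on(chrom)
            for iv in a.on(chrom):
                cur = iv.start
                for biv in b_ivs:
                    if biv.end <= cur:
                        continue
                    if biv.start >= iv.end:
                        break
                    if biv.start > cur:
                        out.append(GenomeInterval(chrom, cur, biv.start))
                    cur = max(cur, biv.end)
                    if cur >= iv.end:
                        break
                if cur < iv.end:
                    out.append(GenomeInterval(chrom, cur, iv.end))
        return IntervalSet(out)

    def overlap_stats(self, other: "IntervalSet") -> Dict[str, float]:
        """Counts, one-directional overlap percentage, and base-level Jaccard."""
        n_a = len(self)
        n_b = len(other)
        n_in = len(self.overlapping(other))
        shared = self.intersect_bases(other)
        union = self.total_bases() + other.total_bases() - shared
        return {
            "n_a": n_a,
            "n_b": n_b,
            "n_a_in_b": n_in,
            "pct_a_in_b": (100.0 * n_in / n_a) if n_a else 0.0,
            "jaccard_bp": (shared / union) if union else 0.0,
        }
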