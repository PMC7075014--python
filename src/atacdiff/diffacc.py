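"""Differential accessibility scoring between two conditions.

The core statistic: depth-normalize the two binned pileups to equal total
signal, form a genome-wide per-bin log2 ratio (with pseudocount), then give
each accessible region a *log2 sum score* — the sum of the FULL value of
every ratio bin the region overlaps by >= 1 bp (``bedtools map -o sum``
semantics, no length weighting).  Regions at or above the threshold tau
(default 15) are reported as more accessible in the test condition, ranked
by score.  Regions accessible only in the test condition come from the
zero-overlap set operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .intervals import GenomeInterval, IntervalSet
from .tracks import CoverageTrack


@dataclass
class ScoredRegion:
    """An accessible region with its log2-sum differential score."""

    region: GenomeInterval
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


def depth_normalize(
    a: CoverageTrack, b: CoverageTrack
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Scale both tracks to signal-per-million (total_signal = 1e6).

    The relative bin profile of each track is unchanged; downstream log2
    ratios become invariant to multiplying either raw track by any positive
    constant.
    """
    if not a.same_grid(b):
        raise ValueError("tracks are on different bin grids")
    ta, tb = a.total_signal, b.total_signal
    if ta <= 0 or tb <= 0:
        raise ValueError("cannot depth-normalize a zero-signal track")
    return (
        a.scaled(1e6 / ta, kind="normalized"),
        b.scaled(1e6 / tb, kind="normalized"),
    )


def log2_ratio_track(
    mut: CoverageTrack, ctrl: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin log2((mut + psi) / (ctrl + psi)), defined on every bin."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not mut.same_grid(ctrl):
        raise ValueError("tracks are on different bin grids")
    data = {
        chrom: np.log2((mut.data[chrom] + pseudocount)
                       / (ctrl.data[chrom] + pseudocount))
        for chrom in mut.data
    }
    return CoverageTrack(binsize=mut.binsize, data=data, kind="log2ratio")


def region_sum_scores(
    ratio: CoverageTrack, regions: IntervalSet | List[GenomeInterval]
) -> List[ScoredRegion]:
    """Sum the full value of every bin a region overlaps by >= 1 bp.

    One ScoredRegion per input region, order preserved.  Partially
    overlapped bins contribute their whole value (no pro-rating), exactly as
    ``bedtools map -o sum`` does on a binned track.
    """
    B = ratio.binsize
    out: List[ScoredRegion] = []
    for iv in regions:
        if iv.chrom not in ratio.data:
            raise KeyError(f"chromosome {iv.chrom!r} absent from ratio track")
        vec = ratio.data[iv.chrom]
        b0 = iv.start // B
        b1 = min((iv.end + B - 1) // B, len(vec))
        out.append(ScoredRegion(iv, float(vec[b0:b1].sum())))
    return out


def select_more_accessible(
    scored: List[ScoredRegion], threshold: float = 15.0
) -> List[ScoredRegion]:
    """Regions with score >= threshold, ranked by descending score.

    The higher the sum score, the more accessible the region is in the test
    condition relative to control; ties break by coordinate.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = [sr for sr in scored if sr.score >= threshold]
    hits.sort(key=lambda sr: (-sr.score, sr.region.key()))
    return hits


def flag_less_accessible(
    scored: List[ScoredRegion],
) -> List[ScoredRegion]:
    """Regions with negative score, flagged sensitivity-confounded.

    Reduced accessibility in a low-input condition is confounded by assay
    sensitivity, so no default threshold is applied on the negative side;
    callers receive the ranked list for inspection only.
    """
    hits = [sr for sr in scored if sr.score < 0]
    hits.sort(key=lambda sr: (sr.score, sr.region.key()))
    for sr in hits:
        sr.region.attrs.setdefault("flag", "sensitivity_confounded")
    return hits


def mutant_exclusive_regions(
    mut_peaks: IntervalSet, ctrl_peaks: IntervalSet
) -> IntervalSet:
    """Peaks of the test condition with zero overlap in the control peak set."""
    return mut_peaks.exclusive(ctrl_peaks)
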