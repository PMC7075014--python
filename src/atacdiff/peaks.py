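"""Enrichment calling from insertion-site pileups.

The caller follows the classic no-control strategy for accessibility data:
each Tn5 cut site is smoothed into a fixed window (``shift``/``extsize``, by
default a 200 bp window centred on the cut), binned coverage is tested per
bin against a local Poisson background lambda_local = max(lambda_genome,
lambda_window), p-values are Benjamini-Hochberg adjusted genome-wide, and
contiguous significant bins are assembled into peaks.  Broad marks are called
by extending strong bins (q <= qcut) through flanking weak bins
(q <= broad_cutoff) and linking runs across small gaps, with an optional
matched input track supplying the local background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import ChromSizes, GenomeInterval
from .tracks import CoverageTrack, n_bins


@dataclass
class Peak:
    """A called narrow enrichment with its summit and significance."""

    chrom: str
    start: int
    end: int
    summit: int
    pvalue: float
    qvalue: float
    fold_enrichment: float
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside peak")
        if not (0 < self.pvalue <= 1) or not (0 < self.qvalue <= 1):
            raise ValueError("p/q values must lie in (0, 1]")

    def interval(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.start, self.end, name=self.name,
            score=min(1000.0, round(-10 * math.log10(max(self.qvalue, 1e-300)), 2)),
            attrs={
                "signalValue": self.fold_enrichment,
                "pValue": -math.log10(max(self.pvalue, 1e-300)),
                "qValue": -math.log10(max(self.qvalue, 1e-300)),
                "peak": self.summit - self.start,
            },
        )


@dataclass
class BroadDomain:
    """A broad enrichment; qvalue is that of the strongest constituent bin."""

    chrom: str
    start: int
    end: int
    qvalue: float
    name: str = "."

    def interval(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.start, self.end, name=self.name,
            score=min(1000.0, round(-10 * math.log10(max(self.qvalue, 1e-300)), 2)),
            attrs={
                "signalValue": 0.0,
                "pValue": -1.0,
                "qValue": -math.log10(max(self.qvalue, 1e-300)),
            },
        )


def cut_site(read: GenomeInterval) -> int:
    """5' cut position of a stranded fragment: start on '+', end-1 on '-'."""
    return read.start if read.strand != "-" else read.end - 1


def aggregate_replicates(
    read_sets: Sequence[Sequence[GenomeInterval]],
) -> List[GenomeInterval]:
    """Pool replicate read lists by order-stable concatenation."""
    if not read_sets:
        raise ValueError("need at least one replicate")
    pooled: List[GenomeInterval] = []
    for reads in read_sets:
        pooled.extend(reads)
    return pooled


def insertion_pileup(
    reads: Sequence[GenomeInterval],
    shift: int,
    extsize: int,
    sizes: ChromSizes,
    binsize: int,
) -> CoverageTrack:
    """Smoothed cut-site coverage on a fixed bin grid.

    Each cut site t contributes unit coverage to [t+shift, t+shift+extsize),
    clipped to the chromosome; a bin's value is covered bases / binsize, so
    total signal x binsize equals the exact unclipped-base count.
    """
    if extsize <= 0:
        raise ValueError("extsize must be > 0")
    cuts: Dict[str, List[int]] = {c: [] for c in sizes}
    for read in reads:
        if read.chrom not in sizes:
            raise KeyError(f"chromosome {read.chrom!r} absent from sizes")
        t = cut_site(read)
        if t < 0 or t >= sizes[read.chrom]:
            raise ValueError(
                f"read cut site {read.chrom}:{t} beyond chromosome end"
            )
        cuts[read.chrom].append(t)

    track = CoverageTrack.zeros(sizes, binsize)
    for chrom, sites in cuts.items():
        if not sites:
            continue
        length = sizes[chrom]
        t = np.asarray(sites, dtype=np.int64)
        s = np.clip(t + shift, 0, length)
        e = np.clip(t + shift + extsize, 0, length)
        nb = n_bins(length, binsize)
        padded = nb * binsize
        delta = np.bincount(s, minlength=padded + 1).astype(np.int64)
        np.subtract.at(delta, e, np.ones_like(e))
        per_base = np.cumsum(delta[:padded])
        track.data[chrom] = (
            per_base.reshape(nb, binsize).sum(axis=1) / binsize
        ).astype(np.float64)
    return track


def _sliding_mean(vec: np.ndarray, half_bins: int) -> np.ndarray:
    """Mean of vec over a window of +-half_bins bins, truncated at the edges."""
    n = len(vec)
    cs = np.concatenate([[0.0], np.cumsum(vec)])
    lo = np.clip(np.arange(n) - half_bins, 0, n)
    hi = np.clip(np.arange(n) + half_bins + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def effective_genome_length(
    sizes: ChromSizes,
    excluded_chroms: Sequence[str] = (),
    blacklist_bases: int = 0,
) -> int:
    """Genome length available to signal: total minus excluded chroms/blacklist."""
    total = sum(l for c, l in sizes.items() if c not in set(excluded_chroms))
    return total - blacklist_bases


def poisson_bin_pvalues(
    track: CoverageTrack,
    sizes: ChromSizes,
    local_window: int = 10_000,
    effective_length: Optional[int] = None,
    control: Optional[CoverageTrack] = None,
) -> Dict[str, np.ndarray]:
    """Per-bin upper-tail Poisson p-values against a local background.

    lambda_local = max(lambda_genome, lambda_window), with the window mean
    taken from the track itself (no-control mode) or from a depth-scaled
    control track when one is supplied.  p = P(Poisson(lambda_local) >= k)
    with k the bin value rounded up.  A zero-signal track yields all ones.
    """
    if track.kind != "raw":
        raise ValueError("p-values are defined on raw-count tracks")
    total = track.total_signal
    out: Dict[str, np.ndarray] = {}
    if total <= 0:
        return {c: np.ones(len(v)) for c, v in track.data.items()}
    eff = effective_length if effective_length else sum(
        sizes[c] for c in track.data
    )
    lam_genome = total * track.binsize / eff
    half_bins = max(0, local_window // (2 * track.binsize))
    if control is not None:
        if not track.same_grid(control):
            raise ValueError("control track grid mismatch")
        ctrl_total = control.total_signal
        if ctrl_total <= 0:
            raise ValueError("control track has zero signal")
        scale = total / ctrl_total
    for chrom, vec in track.data.items():
        if control is not None:
            lam_window = _sliding_mean(control.data[chrom], half_bins) * scale
        else:
            lam_window = _sliding_mean(vec, half_bins)
        lam = np.maximum(lam_genome, lam_window)
        k = np.ceil(vec - 1e-9)
        # extreme tails underflow to exactly 0; clamp into (0, 1]
        out[chrom] = np.clip(stats.poisson.sf(k - 1, lam), 1e-300, 1.0)
    return out


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _genomewide_q(
    pvals: Dict[str, np.ndarray],
) -> Dict[str, np.ndarray]:
    """BH across all bins of all chromosomes jointly (order-invariant)."""
    chroms = sorted(pvals)
    flat = np.concatenate([pvals[c] for c in chroms])
    q = bh_qvalues(flat)
    out: Dict[str, np.ndarray] = {}
    offset = 0
    for c in chroms:
        n = len(pvals[c])
        out[c] = q[offset:offset + n]
        offset += n
    return out


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean vector."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def call_narrow_peaks(
    track: CoverageTrack,
    sizes: ChromSizes,
    qcut: float = 0.05,
    local_window: int = 10_000,
    min_len: Optional[int] = None,
    effective_length: Optional[int] = None,
    blacklist: Sequence[GenomeInterval] = (),
) -> List[Peak]:
    """Assemble narrow peaks from contiguous bins with q <= qcut.

    Summits are the centre of the highest-pileup bin in the run (leftmost on
    ties); fold enrichment is the summit bin value over its lambda_local.
    Peaks shorter than ``min_len`` (default one bin) are dropped, as are
    peaks overlapping the blacklist.
    """
    from .io import filter_excluded  # local import avoids a cycle

    if min_len is None:
        min_len = track.binsize
    pvals = poisson_bin_pvalues(track, sizes, local_window, effective_length)
    qvals = _genomewide_q(pvals)
    B = track.binsize
    peaks: List[Peak] = []
    eff = effective_length if effective_length else sum(sizes[c] for c in track.data)
    total = track.total_signal
    lam_genome = total * B / eff if total > 0 else 0.0
    half_bins = max(0, local_window // (2 * B))
    for chrom in sorted(track.data):
        vec = track.data[chrom]
        q = qvals[chrom]
        p = pvals[chrom]
        lam = np.maximum(lam_genome, _sliding_mean(vec, half_bins))
        for b0, b1 in _runs(q <= qcut):
            start = b0 * B
            end = min(b1 * B, sizes[chrom])
            if end - start < min_len:
                continue
            rel = int(np.argmax(vec[b0:b1]))
            summit_bin = b0 + rel
            summit = min(summit_bin * B + B // 2, sizes[chrom] - 1)
            lam_s = max(lam[summit_bin], 1e-12)
            peaks.append(Peak(
                chrom, start, end, summit,
                pvalue=float(p[b0:b1].min()),
                qvalue=float(q[b0:b1].min()),
                fold_enrichment=float(vec[summit_bin] / lam_s),
            ))
    if blacklist:
        kept_iv, _ = filter_excluded([pk.interval() for pk in peaks], blacklist)
        kept_keys = {(iv.chrom, iv.start, iv.end) for iv in kept_iv}
        peaks = [pk for pk in peaks if (pk.chrom, pk.start, pk.end) in kept_keys]
    for i, pk in enumerate(peaks, 1):
        pk.name = f"peak_{i}"
    return peaks


def call_broad_domains(
    track: CoverageTrack,
    sizes: ChromSizes,
    qcut: float = 0.05,
    broad_cutoff: float = 0.1,
    link_gap: Optional[int] = None,
    local_window: int = 10_000,
    effective_length: Optional[int] = None,
    control: Optional[CoverageTrack] = None,
) -> List[BroadDomain]:
    """Broad-mark domains: weak runs anchored by a strong bin, gap-linked.

    Runs of bins with q <= broad_cutoff are kept only when they contain at
    least one strong bin (q <= qcut); retained runs closer than ``link_gap``
    bp (default 4 bins) are merged.  Domain q-value is the minimum bin q.
    """
    B = track.binsize
    if link_gap is None:
        link_gap = 4 * B
    pvals = poisson_bin_pvalues(track, sizes, local_window, effective_length,
                                control=control)
    qvals = _genomewide_q(pvals)
    domains: List[BroadDomain] = []
    for chrom in sorted(track.data):
        q = qvals[chrom]
        candidates = []
        for b0, b1 in _runs(q <= broad_cutoff):
            if (q[b0:b1] <= qcut).any():
                candidates.append((b0 * B, min(b1 * B, sizes[chrom]),
                                   float(q[b0:b1].min())))
        linked: List[List[float]] = []
        for start, end, qmin in candidates:
            if linked and start - linked[-1][1] <= link_gap:
                linked[-1][1] = end
                linked[-1][2] = min(linked[-1][2], qmin)
            else:
                linked.append([start, end, qmin])
        for start, end, qmin in linked:
            domains.append(BroadDomain(chrom, int(start), int(end), qmin))
    for i, dom in enumerate(domains, 1):
        dom.name = f"domain_{i}"
    return domains
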