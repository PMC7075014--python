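"""Genomic annotation and data integration downstream of region scoring.

Feature classification follows the usual promoter > 5'UTR > 3'UTR > exon >
intron > distal-intergenic priority, with the promoter a fixed window around
the TSS.  Gene linking extends regions +-w (default 10 kb) and takes any
>= 1 bp overlap with a gene span.  Gene-set statistics are exact
hypergeometric tails with Benjamini-Hochberg adjustment across a library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import ScoredRegion
from .intervals import ChromSizes, GenomeInterval, IntervalSet
from .io import GeneModel
from .peaks import BroadDomain, bh_qvalues
from .tracks import CoverageTrack

FEATURE_CLASSES = (
    "promoter", "utr5", "utr3", "exon", "intron", "distal_intergenic"
)


@dataclass
class GeneRegionLink:
    region: GenomeInterval
    gene_id: str
    distance: int  # bp from region to gene span, 0 if overlapping


class FeatureIndex:
    """Per-class interval sets built once from a gene-model set.

    UTRs are the exonic parts outside the CDS (genes without a CDS
    contribute exon/intron only); the exon class is the coding part.
    """

    def __init__(self, genes: Sequence[GeneModel], promoter_window: int):
        if promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")
        self.promoter_window = promoter_window
        prom, utr5, utr3, exon, span = [], [], [], [], []
        for g in genes:
            tss = g.tss
            prom.append(GenomeInterval(
                g.chrom, max(0, tss - promoter_window), tss + promoter_window))
            span.append(g.span())
            for s, e in g.exons:
                if not g.has_cds:
                    exon.append(GenomeInterval(g.chrom, s, e))
                    continue
                left = (s, min(e, g.cds_start))
                mid = (max(s, g.cds_start), min(e, g.cds_end))
                right = (max(s, g.cds_end), e)
                left_cls, right_cls = (
                    ("utr5", "utr3") if g.strand == "+" else ("utr3", "utr5")
                )
                for (lo, hi), cls in ((left, left_cls), (mid, "exon"),
                                      ((right), right_cls)):
                    if hi > lo:
                        {"utr5": utr5, "utr3": utr3, "exon": exon}[cls].append(
                            GenomeInterval(g.chrom, lo, hi))
        self.sets: Dict[str, IntervalSet] = {
            "promoter": IntervalSet(prom).merge(),
            "utr5": IntervalSet(utr5).merge(),
            "utr3": IntervalSet(utr3).merge(),
            "exon": IntervalSet(exon).merge(),
            "intron": IntervalSet(span).subtract(
                IntervalSet(exon + utr5 + utr3)),
        }

    def classify(self, region: GenomeInterval) -> str:
        probe = IntervalSet([region])
        for cls in ("promoter", "utr5", "utr3", "exon", "intron"):
            if len(probe.overlapping(self.sets[cls])):
                return cls
        return "distal_intergenic"


def classify_region(
    region: GenomeInterval,
    genes: Sequence[GeneModel],
    promoter_window: int = 1_000,
    index: Optional[FeatureIndex] = None,
) -> str:
    """Highest-priority feature class the region overlaps (any overlap)."""
    if index is None:
        index = FeatureIndex(genes, promoter_window)
    return index.classify(region)


def genomic_distribution(
    regions: Iterable[GenomeInterval],
    genes: Sequence[GeneModel],
    sizes: ChromSizes,
    promoter_window: int = 1_000,
) -> pd.DataFrame:
    """Feature-class proportions of a region set next to the genome baseline.

    The baseline column is the per-base fraction of the genome falling in
    each class under the same priority, so both columns sum to 1.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty region list")
    index = FeatureIndex(genes, promoter_window)
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for iv in regions:
        counts[index.classify(iv)] += 1
    n = len(regions)

    total = sizes.total_length
    base: Dict[str, float] = {}
    claimed = IntervalSet([])
    for cls in ("promoter", "utr5", "utr3", "exon", "intron"):
        remaining = IntervalSet(
            iv for iv in index.sets[cls] if iv.chrom in sizes
        ).subtract(claimed)
        # promoter windows may run past the chromosome end; clip when counting
        bases = sum(
            max(0, min(iv.end, sizes[iv.chrom]) - iv.start)
            for iv in remaining
        )
        base[cls] = bases / total
        claimed = IntervalSet(list(claimed) + list(remaining)).merge()
    base["distal_intergenic"] = 1.0 - sum(base.values())

    return pd.DataFrame({
        "feature": list(FEATURE_CLASSES),
        "region_fraction": [counts[c] / n for c in FEATURE_CLASSES],
        "genome_fraction": [base[c] for c in FEATURE_CLASSES],
    })


def link_genes(
    regions: Iterable[GenomeInterval],
    genes: Sequence[GeneModel],
    window: int,
    sizes: ChromSizes,
) -> List[GeneRegionLink]:
    """Link every (region, gene) pair whose +-window extension overlaps.

    Equivalent to extending either the region or the gene span by the same
    window.  ``distance`` is the gap between the original spans (0 when they
    overlap); it never exceeds the window.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: List[GeneRegionLink] = []
    for iv in regions:
        if iv.chrom not in sizes:
            raise KeyError(f"chromosome {iv.chrom!r} absent from sizes")
        lo = max(0, iv.start - window)
        hi = min(sizes[iv.chrom], iv.end + window)
        for g in by_chrom.get(iv.chrom, []):
            if g.tx_start < hi and lo < g.tx_end:
                if g.tx_start >= iv.end:
                    dist = g.tx_start - iv.end
                elif g.tx_end <= iv.start:
                    dist = iv.start - g.tx_end
                else:
                    dist = 0
                links.append(GeneRegionLink(iv, g.gene_id, dist))
    return links


def colocate_de(
    scored: Sequence[ScoredRegion],
    de: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int,
    sizes: ChromSizes,
) -> Tuple[List[ScoredRegion], pd.DataFrame]:
    """Regions linked (within +-window) to a differentially expressed gene.

    Returns the region subset (each region counted once) and the per-pair
    table (one row per region-gene link).  DE genes absent from the gene
    models raise a warning, not an error.
    """
    if de.empty:
        raise ValueError("DE table is empty")
    model_ids = {g.gene_id for g in genes}
    missing = sorted(set(de["gene_id"]) - model_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} DE gene ids absent from gene models: "
            f"{missing[:5]}...", stacklevel=2)
    de_map = de.set_index("gene_id")
    links = link_genes([sr.region for sr in scored], genes, window, sizes)
    score_by_key = {sr.region.key(): sr for sr in scored}
    rows = []
    hit_keys = []
    for link in links:
        if link.gene_id not in de_map.index:
            continue
        sr = score_by_key[link.region.key()]
        rows.append({
            "chrom": link.region.chrom,
            "start": link.region.start,
            "end": link.region.end,
            "region": link.region.name,
            "gene_id": link.gene_id,
            "distance": link.distance,
            "score": sr.score,
            "log2fc": float(de_map.loc[link.gene_id, "log2fc"]),
            "direction": str(de_map.loc[link.gene_id, "direction"]),
        })
        hit_keys.append(link.region.key())
    seen = set()
    region_hits = []
    for key in hit_keys:
        if key not in seen:
            seen.add(key)
            region_hits.append(score_by_key[key])
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region", "gene_id",
                       "distance", "score", "log2fc", "direction"])
    return region_hits, table


def colocate_marks(
    regions: Iterable[GenomeInterval],
    domains: Sequence[BroadDomain] | Sequence[GenomeInterval] | IntervalSet,
) -> List[Tuple[GenomeInterval, int]]:
    """Regions with >= 1 bp overlap in the mark set, with overlap base count."""
    if isinstance(domains, IntervalSet):
        dom_set = domains
    else:
        dom_set = IntervalSet(
            d.interval() if isinstance(d, BroadDomain) else d for d in domains
        )
    flat = dom_set.merge()
    out: List[Tuple[GenomeInterval, int]] = []
    for iv in regions:
        bp = 0
        for dom in flat.on(iv.chrom):
            if dom.start >= iv.end:
                break
            lo, hi = max(dom.start, iv.start), min(dom.end, iv.end)
            if hi > lo:
                bp += hi - lo
        if bp > 0:
            out.append((iv, bp))
    return out


def signature_overlap(
    gene_set_a: Set[str], gene_set_b: Set[str], universe: Set[str]
) -> Dict[str, float]:
    """Overlap of two gene sets with an exact hypergeometric upper tail.

    p = P(X >= n_overlap) for X ~ Hypergeometric(|universe|, |b|, |a|).
    """
    for label, s in (("a", gene_set_a), ("b", gene_set_b)):
        extra = sorted(s - universe)
        if extra:
            raise ValueError(
                f"gene set {label} not a subset of universe: {extra[:5]}")
    n_a, n_b = len(gene_set_a), len(gene_set_b)
    k = len(gene_set_a & gene_set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), n_b, n_a))
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_overlap": k,
        "fraction_of_a": (k / n_a) if n_a else 0.0,
        "p_value": min(1.0, p),
    }


def geneset_enrichment(
    query_genes: Set[str],
    library: Dict[str, Set[str]],
    universe: Set[str],
) -> pd.DataFrame:
    """Over-representation of a query gene list in each library set.

    One row per set with overlap, odds ratio (a*d)/(b*c) on the 2x2 table,
    exact hypergeometric p and BH q; rows sorted by (p, name).
    """
    if not query_genes:
        raise ValueError("empty query gene list")
    if not library:
        raise ValueError("empty gene-set library")
    query = set(query_genes) & universe
    rows = []
    for name, genes in library.items():
        s = set(genes) & universe
        a = len(query & s)
        b = len(query - s)
        c = len(s - query)
        d = len(universe) - a - b - c
        if a == 0:
            odds = 0.0
        elif b * c == 0:
            odds = float("inf")
        else:
            odds = (a * d) / (b * c)
        p = float(stats.hypergeom.sf(a - 1, len(universe), len(s), len(query)))
        rows.append({"set": name, "n_set": len(s), "overlap": a,
                     "odds_ratio": odds, "p_value": min(1.0, p)})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "set"]).reset_index(drop=True)


def _window_mean(vec: np.ndarray, binsize: int, x0: float, x1: float) -> float:
    """Mean of the piecewise-constant track over real interval [x0, x1).

    Bases outside the track contribute 0; the denominator is the full
    window length.
    """
    if x1 <= x0:
        return 0.0
    span = x1 - x0
    lo = max(x0, 0.0)
    hi = min(x1, len(vec) * binsize)
    if hi <= lo:
        return 0.0
    b0 = int(lo // binsize)
    b1 = int(np.ceil(hi / binsize))
    total = 0.0
    for b in range(b0, b1):
        o_lo = max(lo, b * binsize)
        o_hi = min(hi, (b + 1) * binsize)
        if o_hi > o_lo:
            total += vec[b] * (o_hi - o_lo)
    return total / span


def coverage_matrix(
    track: CoverageTrack,
    regions: Sequence[GenomeInterval],
    mode: str = "center",
    flank: int = 1_000,
    nbins: int = 50,
    scores: Optional[Sequence[float]] = None,
    row_normalize: bool = False,
) -> Tuple[np.ndarray, List[int], np.ndarray]:
    """Per-region signal matrix for heat-map style summaries.

    center mode: ``nbins`` equal windows across [midpoint - flank,
    midpoint + flank); scale mode: the region body rescaled to ``nbins``
    windows.  Cell values are mean track signal per window; windows running
    off the chromosome treat missing bases as 0.  Rows are ordered by
    descending score when scores are given (ties by coordinate), else input
    order.  Returns (matrix, row order as input indices, window offsets).
    """
    if nbins <= 0:
        raise ValueError("nbins must be > 0")
    if mode not in ("center", "scale"):
        raise ValueError(f"unknown mode {mode!r}")
    order = list(range(len(regions)))
    if scores is not None:
        if len(scores) != len(regions):
            raise ValueError("scores length mismatch")
        order.sort(key=lambda i: (-scores[i], regions[i].key()))
    mat = np.zeros((len(regions), nbins))
    for row, i in enumerate(order):
        iv = regions[i]
        vec = track.data[iv.chrom]
        if mode == "center":
            mid = (iv.start + iv.end) / 2.0
            edges = np.linspace(mid - flank, mid + flank, nbins + 1)
        else:
            edges = np.linspace(iv.start, iv.end, nbins + 1)
        for j in range(nbins):
            mat[row, j] = _window_mean(vec, track.binsize,
                                       edges[j], edges[j + 1])
    if row_normalize:
        peak = np.abs(mat).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        mat = mat / peak
    if mode == "center":
        offsets = (np.linspace(-flank, flank, nbins + 1)[:-1]
                   + flank / nbins)
    else:
        offsets = np.linspace(0, 1, nbins + 1)[:-1] + 0.5 / nbins
    return mat, order, offsets
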