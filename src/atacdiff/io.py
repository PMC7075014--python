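"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported dialects: BED3/6, narrowPeak (BED6+4), broadPeak (BED6+3), bedGraph,
two-column chrom.sizes, BED12 or BED6 gene models, a TSV differential
expression table and GMT gene-set libraries.  All coordinates are 0-based
half-open everywhere, unchanged on input and output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomeInterval, IntervalSet
from .tracks import CoverageTrack, n_bins

DIALECTS = ("BED", "narrowPeak", "broadPeak")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> ChromSizes:
    sizes = ChromSizes()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    Path(path).write_text(
        "".join(f"{chrom}\t{length}\n" for chrom, length in sizes.items())
    )


# ---------------------------------------------------------------------------
# BED / narrowPeak / broadPeak
# ---------------------------------------------------------------------------

def _parse_score(tok: str) -> float | None:
    return None if tok == "." else float(tok)


def read_intervals(path, dialect: str | None = None) -> List[GenomeInterval]:
    """Read BED-like records in file order.

    The dialect is inferred from the column count when not given (10 columns
    -> narrowPeak, 9 -> broadPeak); extra columns are preserved in
    ``attrs`` (keys ``signalValue``, ``pValue``, ``qValue`` and, for
    narrowPeak, ``peak`` — the summit offset).
    """
    records: List[GenomeInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
        try:
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
            name = f[3] if len(f) > 3 else "."
            score = _parse_score(f[4]) if len(f) > 4 else None
            strand = f[5] if len(f) > 5 else "."
            attrs: dict = {}
            ncol = len(f)
            dia = dialect
            if dia is None:
                dia = {10: "narrowPeak", 9: "broadPeak"}.get(ncol, "BED")
            if dia in ("narrowPeak", "broadPeak") and ncol >= 9:
                attrs["signalValue"] = float(f[6])
                attrs["pValue"] = float(f[7])
                attrs["qValue"] = float(f[8])
                if dia == "narrowPeak" and ncol >= 10:
                    attrs["peak"] = int(f[9])
            records.append(
                GenomeInterval(f[0], start, end, name=name, score=score,
                               strand=strand, attrs=attrs)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _fmt(x: float | None, default: str = ".") -> str:
    if x is None:
        return default
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_intervals(records: Iterable[GenomeInterval], dialect: str, path) -> None:
    """Write records in the given dialect; round-trips with read_intervals."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for iv in records:
        cols = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                _fmt(iv.score, "0"), iv.strand]
        if dialect in ("narrowPeak", "broadPeak"):
            cols += [
                _fmt(iv.attrs.get("signalValue", 0.0)),
                _fmt(iv.attrs.get("pValue", -1.0)),
                _fmt(iv.attrs.get("qValue", -1.0)),
            ]
            if dialect == "narrowPeak":
                cols.append(str(int(iv.attrs.get("peak", -1))))
        lines.append("\t".join(cols))
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_track(path, sizes: ChromSizes, binsize: int) -> CoverageTrack:
    """Resample a bedGraph onto a fixed grid by length-weighted mean.

    Uncovered bases contribute value 0.  Overlapping records or chromosomes
    absent from ``sizes`` are errors.
    """
    if binsize <= 0:
        raise ValueError("binsize must be > 0")
    track = CoverageTrack.zeros(sizes, binsize)
    last_end: Dict[str, int] = {}
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {c: [] for c in sizes}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if chrom not in sizes:
            raise ParseError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
        if start >= end:
            raise ParseError(f"{path}: line {lineno}: start >= end")
        per_chrom[chrom].append((start, end, value))
    for chrom, recs in per_chrom.items():
        recs.sort()
        prev_end = 0
        vec = track.data[chrom]
        length = sizes[chrom]
        for start, end, value in recs:
            if start < prev_end:
                raise ParseError(f"{path}: overlapping bedGraph records on {chrom}")
            prev_end = end
            if value == 0.0:
                continue
            b0, b1 = start // binsize, (end + binsize - 1) // binsize
            for b in range(b0, b1):
                lo = max(start, b * binsize)
                hi = min(end, (b + 1) * binsize)
                # the last bin of a chromosome may be partial; weight by
                # the bases it actually contains
                width = min((b + 1) * binsize, length) - b * binsize
                vec[b] += value * (hi - lo) / width
    return track


def write_track(track: CoverageTrack, sizes: ChromSizes, path,
                precision: int = 6) -> None:
    """Write a track as bedGraph, run-length compressing equal adjacent bins."""
    lines = []
    B = track.binsize
    for chrom, vec in track.data.items():
        length = sizes[chrom]
        run_start = 0
        run_val = vec[0] if len(vec) else 0.0
        for i in range(1, len(vec) + 1):
            v = vec[i] if i < len(vec) else None
            if v is None or v != run_val:
                if run_val != 0.0:
                    lines.append(
                        f"{chrom}\t{run_start * B}\t{min(i * B, length)}\t"
                        f"{round(float(run_val), precision):g}"
                    )
                run_start, run_val = i, v
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A transcript model; TSS is txStart on '+' and txEnd-1 on '-'."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: txStart >= txEnd")
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]
        self.exons = sorted(self.exons)
        prev = self.tx_start
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if s < prev:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None and self.cds_start > self.cds_end:
            raise ValueError(f"gene {self.gene_id}: cdsStart > cdsEnd")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_start < self.cds_end

    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.tx_start, self.tx_end,
                              name=self.gene_id, strand=self.strand)


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from BED12 (exons + CDS) or BED6 (span only)."""
    genes: List[GeneModel] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        try:
            if len(f) >= 12:
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                count = int(f[9])
                bsizes = [int(x) for x in f[10].rstrip(",").split(",")]
                bstarts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(bsizes) != count or len(bstarts) != count:
                    raise ValueError("block count mismatch")
                exons = [(start + bs, start + bs + sz)
                         for bs, sz in zip(bstarts, bsizes)]
                cds_s, cds_e = (thick_s, thick_e) if thick_s < thick_e else (None, None)
                genes.append(GeneModel(name, chrom, strand, start, end,
                                       cds_s, cds_e, exons))
            elif len(f) >= 6:
                genes.append(GeneModel(f[3], f[0], f[5], int(f[1]), int(f[2])))
            else:
                raise ValueError("expected BED6 or BED12")
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    lines = []
    for g in genes:
        bsizes = ",".join(str(e - s) for s, e in g.exons) + ","
        bstarts = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
        cds_s = g.cds_start if g.has_cds else g.tx_start
        cds_e = g.cds_end if g.has_cds else g.tx_start
        lines.append("\t".join(map(str, [
            g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
            cds_s, cds_e, "0,0,0", len(g.exons), bsizes, bstarts,
        ])))
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# DE table and gene sets
# ---------------------------------------------------------------------------

def read_de_table(path) -> pd.DataFrame:
    """Read a TSV with columns gene_id, log2fc, padj; adds a direction column.

    ``direction`` is 'up' for genes higher in the mutant (log2fc > 0), else
    'down'.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ParseError(f"{path}: padj outside [0, 1]")
    df = df.copy()
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df


def write_de_table(df: pd.DataFrame, path) -> None:
    df.loc[:, ["gene_id", "log2fc", "padj"]].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}: line {lineno}: GMT needs name, desc, genes")
        genes = {g for g in f[2:] if g}
        if not genes:
            raise ParseError(f"{path}: line {lineno}: empty gene set {f[0]!r}")
        sets[f[0]] = genes
    return sets


def write_gmt(sets: Dict[str, Iterable[str]], path) -> None:
    lines = [
        "\t".join([name, name] + sorted(set(genes)))
        for name, genes in sets.items()
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Blacklist / chromosome exclusion
# ---------------------------------------------------------------------------

def filter_excluded(
    records: Sequence[GenomeInterval],
    blacklist: Iterable[GenomeInterval] = (),
    excluded_chroms: Iterable[str] = (),
) -> Tuple[List[GenomeInterval], int]:
    """Drop records on excluded chromosomes or overlapping a blacklist interval.

    Any overlap (>= 1 bp) with the blacklist removes a record; bookended
    records are kept.  Survivor order is preserved.  Returns (kept, n_removed).
    """
    excluded = set(excluded_chroms)
    black = IntervalSet(blacklist).merge()
    kept: List[GenomeInterval] = []
    for iv in records:
        if iv.chrom in excluded:
            continue
        hit = False
        for biv in black.on(iv.chrom):
            if biv.start >= iv.end:
                break
            if biv.end > iv.start:
                hit = True
                break
        if not hit:
            kept.append(iv)
    return kept, len(records) - len(kept)
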