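"""Synthetic two-condition accessibility data with planted ground truth.

The generator emulates the study design the pipeline targets: sparse Tn5
cut-site data from two conditions with a Poisson background, planted
accessible regions that are shared, condition-exclusive, or fold-changed
(extra 2**delta cut rate in the test condition), an optional 25-fold depth
asymmetry between conditions, broad repressive-mark domains over a fraction
of the fold-changed regions, point-source TF peaks at promoter-planted
regions, and a matched differential-expression table with a lineage
signature built to overlap the DE genes at a configured fraction.

Every output is a pure function of (config, seed): re-running bit-reproduces
all fixture files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .intervals import ChromSizes, GenomeInterval, IntervalSet
from .io import GeneModel

CATEGORIES = ("shared", "mutant_only", "control_only", "fold_changed")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic fixture.

    Rates are cut sites per bp at unit depth; per-condition expected counts
    are rate x depth x length.  The depth fields emulate the cell-number
    asymmetry of the emulated design (a low-input test condition vs an
    abundant control) when ``depth_asymmetry`` is on.
    """

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_genes: int = 200
    n_shared: int = 20
    n_mutant_only: int = 20
    n_control_only: int = 0
    n_fold_changed: int = 20
    region_length: Tuple[int, int] = (400, 800)
    background_rate: float = 0.002
    depth_mutant: float = 5.0
    depth_control: float = 5.0
    depth_asymmetry: bool = False  # mutant depth = control depth / 25
    delta: float = 2.0
    enrichment: float = 10.0
    enrichment_levels: Optional[Sequence[float]] = None
    promoter_fraction: float = 0.6  # fold_changed regions placed at TSSs
    min_region_gap: int = 5_000
    fragment_length: int = 50
    # ChIP layer
    chip_depth: float = 5.0
    domain_fraction: float = 0.5  # fold_changed regions under a broad domain
    n_random_domains: int = 5
    domain_length: Tuple[int, int] = (5_000, 15_000)
    domain_enrichment: float = 8.0
    tf_fraction: float = 0.5  # promoter-planted fold regions with a TF peak
    n_random_tf_peaks: int = 10
    tf_peak_width: int = 250
    tf_enrichment: float = 20.0
    # expression layer
    gene_window: int = 10_000
    de_prob: float = 0.8
    n_de: int = 80
    signature_overlap_fraction: float = 0.30
    signature_size: int = 60
    # artifacts
    n_blacklist: int = 2
    blacklist_length: int = 5_000
    blacklist_enrichment: float = 50.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.depth_control <= 0 or self.depth_mutant <= 0:
            raise ValueError("depths must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def mutant_depth(self) -> float:
        return (self.depth_control / 25.0 if self.depth_asymmetry
                else self.depth_mutant)


@dataclass
class PlantedRegion:
    chrom: str
    start: int
    end: int
    category: str
    delta: float
    rate_mut: float
    rate_ctrl: float
    at_promoter: bool = False

    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end,
                              name=f"{self.category}")


@dataclass
class Truth:
    regions: List[PlantedRegion] = field(default_factory=list)
    blacklist: List[GenomeInterval] = field(default_factory=list)
    domains: List[GenomeInterval] = field(default_factory=list)
    tf_peaks: List[GenomeInterval] = field(default_factory=list)
    de_up_genes: List[str] = field(default_factory=list)

    def by_category(self, category: str) -> IntervalSet:
        return IntervalSet(
            r.interval() for r in self.regions if r.category == category)

    def to_json(self) -> dict:
        return {
            "regions": [asdict(r) for r in self.regions],
            "blacklist": [[b.chrom, b.start, b.end] for b in self.blacklist],
            "domains": [[d.chrom, d.start, d.end] for d in self.domains],
            "tf_peaks": [[t.chrom, t.start, t.end] for t in self.tf_peaks],
            "de_up_genes": list(self.de_up_genes),
        }


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_toy_genome(config: GeneratorConfig) -> Tuple[ChromSizes, List[GeneModel]]:
    """Deterministic toy genome: non-overlapping multi-exon genes, both strands."""
    rng = np.random.default_rng(config.seed)
    sizes = ChromSizes(config.chrom_lengths)
    chroms = list(sizes)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    genes: List[GeneModel] = []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        length = sizes[chrom]
        slot = length // n
        if slot < 3_000:
            raise ValueError(
                f"genome too small to place {n} genes on {chrom}")
        for i in range(n):
            span = int(rng.integers(2_000, min(8_000, slot - 500)))
            lo = i * slot + 200
            hi = (i + 1) * slot - span - 200
            tx_start = int(rng.integers(lo, max(lo + 1, hi)))
            tx_end = tx_start + span
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 1, tx_end - 1), size=2 * n_ex - 2,
                replace=False))
            bounds = [tx_start, *cuts.tolist(), tx_end]
            exons = [(bounds[2 * k], bounds[2 * k + 1]) for k in range(n_ex)]
            cds_start = exons[0][0] + min(100, (exons[0][1] - exons[0][0]) // 2)
            cds_end = exons[-1][1] - min(100, (exons[-1][1] - exons[-1][0]) // 2)
            if cds_start >= cds_end:
                cds_start, cds_end = tx_start, tx_end
            genes.append(GeneModel(
                f"gene_{len(genes) + 1:04d}", chrom, strand, tx_start, tx_end,
                cds_start, cds_end, exons))
    return sizes, genes


# ---------------------------------------------------------------------------
# placement and read sampling helpers
# ---------------------------------------------------------------------------

def _place_regions(
    rng: np.random.Generator,
    sizes: ChromSizes,
    existing: List[Tuple[str, int, int]],
    n: int,
    lengths: Tuple[int, int],
    min_gap: int,
    at: Optional[List[Tuple[str, int]]] = None,
) -> List[Tuple[str, int, int]]:
    """Place n intervals, min_gap away from existing ones.

    ``at`` pins placements to given (chrom, centre) anchors; otherwise
    placement is uniform with rejection.
    """
    chroms = list(sizes)
    placed: List[Tuple[str, int, int]] = []
    for i in range(n):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        for _attempt in range(1_000):
            if at is not None:
                chrom, centre = at[i]
                start = max(0, centre - length // 2)
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, sizes[chrom] - length))
            end = min(start + length, sizes[chrom])
            ok = all(
                c != chrom or not (start - min_gap < e and s < end + min_gap)
                for c, s, e in existing + placed
            )
            if ok:
                placed.append((chrom, start, end))
                break
            if at is not None:
                # anchored placement that collides: nudge to a new anchor
                at[i] = (chrom, int(rng.integers(min_gap, sizes[chrom] - min_gap)))
        else:
            raise RuntimeError("could not place region; genome too crowded")
    return placed


def _sample_reads(
    rng: np.random.Generator,
    sizes: ChromSizes,
    background_rate: float,
    hot: Sequence[Tuple[str, int, int, float]],
    depth: float,
    fragment_length: int,
) -> List[GenomeInterval]:
    """Poisson cut sites: uniform background plus extra rate in hot intervals.

    ``hot`` entries are (chrom, start, end, extra_rate).  Fragments are
    emitted as stranded BED records whose 5' end is the cut site.
    """
    cuts: List[Tuple[str, int]] = []
    for chrom, length in sizes.items():
        n_bg = rng.poisson(background_rate * depth * length)
        cuts.extend((chrom, int(t)) for t in rng.integers(0, length, n_bg))
    for chrom, start, end, extra in hot:
        if extra <= 0:
            continue
        n = rng.poisson(extra * depth * (end - start))
        cuts.extend((chrom, int(t)) for t in rng.integers(start, end, n))
    strands = rng.random(len(cuts)) < 0.5
    reads = []
    for (chrom, t), plus in zip(cuts, strands):
        length = sizes[chrom]
        if plus:
            reads.append(GenomeInterval(
                chrom, t, min(t + fragment_length, length), strand="+"))
        else:
            reads.append(GenomeInterval(
                chrom, max(0, t - fragment_length + 1), t + 1, strand="-"))
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return reads


def simulate_uniform_reads(
    sizes: ChromSizes, rate: float, seed: int, fragment_length: int = 50
) -> List[GenomeInterval]:
    """Homogeneous-Poisson cut sites at ``rate`` cuts/bp (null model)."""
    rng = np.random.default_rng(seed)
    return _sample_reads(rng, sizes, rate, [], 1.0, fragment_length)


def subsample_reads(
    reads: Sequence[GenomeInterval], fraction: float, seed: int
) -> List[GenomeInterval]:
    """Bernoulli subsample of a read list (emulates fewer input cells)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


# ---------------------------------------------------------------------------
# ATAC layer
# ---------------------------------------------------------------------------

def simulate_atac(
    config: GeneratorConfig,
    sizes: ChromSizes,
    genes: Sequence[GeneModel],
) -> Tuple[List[GenomeInterval], List[GenomeInterval], Truth]:
    """Two-condition cut-site data with planted regions and blacklist artifacts."""
    rng = np.random.default_rng(config.seed + 1)
    bg = config.background_rate
    E_levels = (list(config.enrichment_levels)
                if config.enrichment_levels else [config.enrichment])

    truth = Truth()
    existing: List[Tuple[str, int, int]] = []

    # blacklist artifact regions first, away from everything else
    black = _place_regions(
        rng, sizes, existing, config.n_blacklist,
        (config.blacklist_length, config.blacklist_length),
        config.min_region_gap)
    truth.blacklist = [GenomeInterval(c, s, e, name="blacklist")
                       for c, s, e in black]
    existing += black

    # promoter anchors for a fraction of the fold_changed regions
    n_at_prom = int(round(config.promoter_fraction * config.n_fold_changed))
    prom_genes = (list(rng.choice(len(genes), size=n_at_prom, replace=False))
                  if n_at_prom else [])
    anchors = [(genes[i].chrom, genes[i].tss) for i in prom_genes]

    plan = [
        ("fold_changed", n_at_prom, anchors),
        ("fold_changed", config.n_fold_changed - n_at_prom, None),
        ("shared", config.n_shared, None),
        ("mutant_only", config.n_mutant_only, None),
        ("control_only", config.n_control_only, None),
    ]
    k = 0
    for category, n, at in plan:
        placed = _place_regions(rng, sizes, existing, n, config.region_length,
                                config.min_region_gap, at=at)
        existing += placed
        for chrom, start, end in placed:
            E = E_levels[k % len(E_levels)]
            k += 1
            if category == "shared":
                rm = rc = bg * E
                d = 0.0
            elif category == "mutant_only":
                rm, rc, d = bg * E, bg, float(np.log2(E))
            elif category == "control_only":
                rm, rc, d = bg, bg * E, float(-np.log2(E))
            else:  # fold_changed
                rc = bg * E
                rm = bg * E * 2.0 ** config.delta
                d = config.delta
            truth.regions.append(PlantedRegion(
                chrom, start, end, category, d, rm, rc,
                at_promoter=at is not None))

    def hot(condition: str):
        rate = {"mut": lambda r: r.rate_mut, "ctrl": lambda r: r.rate_ctrl}
        h = [(r.chrom, r.start, r.end, rate[condition](r) - bg)
             for r in truth.regions]
        h += [(b.chrom, b.start, b.end, bg * (config.blacklist_enrichment - 1))
              for b in truth.blacklist]
        return h

    mut_reads = _sample_reads(rng, sizes, bg, hot("mut"),
                              config.mutant_depth, config.fragment_length)
    ctrl_reads = _sample_reads(rng, sizes, bg, hot("ctrl"),
                               config.depth_control, config.fragment_length)
    return mut_reads, ctrl_reads, truth


# ---------------------------------------------------------------------------
# ChIP layer
# ---------------------------------------------------------------------------

def simulate_chip(
    config: GeneratorConfig,
    sizes: ChromSizes,
    genes: Sequence[GeneModel],
    truth: Truth,
) -> Dict[str, List[GenomeInterval]]:
    """Broad-mark, input and TF point-source reads over the planted truth.

    Broad domains (multi-kb elevations) cover a configured fraction of the
    fold_changed regions plus random placements; TF peaks (<= ~300 bp) sit on
    a fraction of the promoter-planted fold_changed regions plus random
    promoters.  A matched input/background read set is emitted for the
    broad mark.
    """
    rng = np.random.default_rng(config.seed + 2)
    bg = config.background_rate
    fold = [r for r in truth.regions if r.category == "fold_changed"]
    n_over = int(round(config.domain_fraction * len(fold)))
    chosen = (list(rng.choice(len(fold), size=n_over, replace=False))
              if n_over else [])

    domains: List[Tuple[str, int, int]] = []
    for i in chosen:
        r = fold[i]
        length = int(rng.integers(*config.domain_length))
        lead = int(rng.integers(0, max(1, length - (r.end - r.start))))
        start = max(0, r.start - lead)
        end = min(sizes[r.chrom], start + length)
        domains.append((r.chrom, start, end))
    domains += _place_regions(rng, sizes, domains, config.n_random_domains,
                              config.domain_length, 2_000)
    # flatten so planted domains are disjoint
    truth.domains = [
        GenomeInterval(iv.chrom, iv.start, iv.end, name="domain")
        for iv in IntervalSet(
            GenomeInterval(c, s, e) for c, s, e in domains).merge()
    ]

    prom_fold = [r for r in fold if r.at_promoter]
    n_tf = int(round(config.tf_fraction * len(prom_fold)))
    tf_sites = [prom_fold[i] for i in (
        rng.choice(len(prom_fold), size=n_tf, replace=False) if n_tf else [])]
    tf_peaks = [
        ((r.start + r.end) // 2 - config.tf_peak_width // 2, r.chrom)
        for r in tf_sites
    ]
    tf_intervals = [
        GenomeInterval(chrom, max(0, c), max(0, c) + config.tf_peak_width,
                       name="tf_peak")
        for c, chrom in tf_peaks
    ]
    other_genes = rng.choice(len(genes), size=config.n_random_tf_peaks,
                             replace=False)
    for gi in other_genes:
        g = genes[gi]
        start = max(0, g.tss - config.tf_peak_width // 2)
        tf_intervals.append(GenomeInterval(
            g.chrom, start, min(sizes[g.chrom], start + config.tf_peak_width),
            name="tf_peak"))
    truth.tf_peaks = sorted(tf_intervals, key=lambda iv: iv.key())

    k27_hot = [(d.chrom, d.start, d.end, bg * (config.domain_enrichment - 1))
               for d in truth.domains]
    tf_hot = [(t.chrom, t.start, t.end, bg * (config.tf_enrichment - 1))
              for t in truth.tf_peaks]
    return {
        "k27": _sample_reads(rng, sizes, bg, k27_hot, config.chip_depth,
                             config.fragment_length),
        "k27_input": _sample_reads(rng, sizes, bg, [], config.chip_depth,
                                   config.fragment_length),
        "tf": _sample_reads(rng, sizes, bg, tf_hot, config.chip_depth,
                            config.fragment_length),
    }


# ---------------------------------------------------------------------------
# expression layer
# ---------------------------------------------------------------------------

def make_de_table(
    genes: Sequence[GeneModel],
    truth: Truth,
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, Dict[str, Set[str]]]:
    """DE table matched to the planted truth, plus signature gene sets.

    Genes within the gene window of a fold_changed or mutant_only region are
    up-regulated with probability ``de_prob``; the table is padded with
    random genes to ``n_de`` rows.  The 'multilineage' signature is built to
    overlap the DE genes at ``signature_overlap_fraction``.
    """
    rng = np.random.default_rng(config.seed + 3)
    w = config.gene_window
    affected = IntervalSet(
        r.interval() for r in truth.regions
        if r.category in ("fold_changed", "mutant_only"))
    de_up: List[str] = []
    for g in genes:
        near = any(
            iv.start - w < g.tx_end and g.tx_start < iv.end + w
            for iv in affected.on(g.chrom))
        if near and rng.random() < config.de_prob:
            de_up.append(g.gene_id)
    all_ids = [g.gene_id for g in genes]
    pool = [gid for gid in all_ids if gid not in set(de_up)]
    n_extra = max(0, config.n_de - len(de_up))
    extra = list(rng.choice(pool, size=min(n_extra, len(pool)), replace=False))
    rows = []
    for gid in de_up:
        rows.append((gid, float(rng.uniform(1, 4)), "up"))
    for gid in extra:
        if rng.random() < 0.5:
            rows.append((gid, float(rng.uniform(1, 4)), "up"))
        else:
            rows.append((gid, float(-rng.uniform(1, 4)), "down"))
    df = pd.DataFrame({
        "gene_id": [r[0] for r in rows],
        "log2fc": [r[1] for r in rows],
        "padj": [float(10 ** -rng.uniform(2, 8)) for _ in rows],
    })
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    truth.de_up_genes = df.loc[df["direction"] == "up", "gene_id"].tolist()

    de_ids = df["gene_id"].tolist()
    k = int(round(config.signature_overlap_fraction * len(de_ids)))
    sig = set(rng.choice(de_ids, size=min(k, len(de_ids)), replace=False))
    non_de = [gid for gid in all_ids if gid not in set(de_ids)]
    fill = max(0, config.signature_size - len(sig))
    sig |= set(rng.choice(non_de, size=min(fill, len(non_de)), replace=False))
    control_set = set(rng.choice(all_ids, size=min(config.signature_size,
                                                   len(all_ids)),
                                 replace=False))
    signatures = {"multilineage": sig, "random_control": control_set}
    return df, signatures


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------

def write_fixture(outdir, config: GeneratorConfig) -> Dict[str, object]:
    """Generate the full fixture directory; returns paths, truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes, genes = make_toy_genome(config)
    mut, ctrl, truth = simulate_atac(config, sizes, genes)
    chip = simulate_chip(config, sizes, genes, truth)
    de, signatures = make_de_table(genes, truth, config)

    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "genes": outdir / "genes.bed12",
        "reads_mut": outdir / "reads_mut.bed",
        "reads_ctrl": outdir / "reads_ctrl.bed",
        "k27_reads": outdir / "k27_reads.bed",
        "k27_input": outdir / "k27_input.bed",
        "tf_reads": outdir / "nfyb_reads.bed",
        "blacklist": outdir / "blacklist.bed",
        "de_table": outdir / "de_table.tsv",
        "signatures": outdir / "signatures.gmt",
        "truth": outdir / "truth.json",
    }
    aio.write_chrom_sizes(sizes, paths["chrom_sizes"])
    aio.write_gene_models(genes, paths["genes"])
    aio.write_intervals(mut, "BED", paths["reads_mut"])
    aio.write_intervals(ctrl, "BED", paths["reads_ctrl"])
    aio.write_intervals(chip["k27"], "BED", paths["k27_reads"])
    aio.write_intervals(chip["k27_input"], "BED", paths["k27_input"])
    aio.write_intervals(chip["tf"], "BED", paths["tf_reads"])
    aio.write_intervals(truth.blacklist, "BED", paths["blacklist"])
    aio.write_de_table(de, paths["de_table"])
    aio.write_gmt(signatures, paths["signatures"])
    paths["truth"].write_text(
        json.dumps(truth.to_json(), indent=1, sort_keys=True))
    return {"paths": {k: str(v) for k, v in paths.items()},
            "truth": truth, "sizes": sizes, "genes": genes,
            "de": de, "signatures": signatures,
            "reads": {"mut": mut, "ctrl": ctrl, **chip}}
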