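"""End-to-end orchestration: reads in, report tables out.

Stage order: filter -> aggregate replicates -> pileup -> peak calling (both
conditions) -> overlap stats -> exclusive regions -> depth normalization ->
log2 ratio -> region scores -> threshold filter -> feature classification ->
gene linking -> DE / mark / TF co-location -> signature overlap -> gene-set
enrichment -> coverage matrices.  Every stage logs its input/output counts;
outputs are deterministic functions of the inputs and config (re-runs are
byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate, diffacc, io as aio, peaks as pk
from .config import PipelineConfig
from .intervals import ChromSizes, GenomeInterval, IntervalSet

log = logging.getLogger("atacdiff")

MANDATORY = ("reads_mutant", "reads_control", "genes", "chrom_sizes")
OPTIONAL = ("blacklist", "k27_reads", "k27_input", "tf_reads", "de_table",
            "signatures")


class InputError(ValueError):
    pass


@dataclass
class AnalysisReport:
    """Headline quantities and exported artifact paths of one pipeline run."""

    config: dict
    n_reads_mutant: int = 0
    n_reads_control: int = 0
    n_filtered_mutant: int = 0
    n_filtered_control: int = 0
    n_peaks_mutant: int = 0
    n_peaks_control: int = 0
    pct_mutant_in_control: float = 0.0
    pct_control_in_mutant: float = 0.0
    jaccard_bp: float = 0.0
    n_mutant_exclusive: int = 0
    n_scored_regions: int = 0
    n_more_accessible: int = 0
    n_less_accessible_flagged: int = 0
    n_de_colocated_regions: Optional[int] = None
    n_de_colocated_genes: Optional[int] = None
    n_k27_domains: Optional[int] = None
    n_k27_colocated: Optional[int] = None
    n_tf_peaks: Optional[int] = None
    n_tf_colocated: Optional[int] = None
    signature_overlap: Optional[dict] = None
    distributions: Dict[str, list] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        counts = [self.n_peaks_mutant, self.n_peaks_control,
                  self.n_mutant_exclusive, self.n_more_accessible]
        if any(c < 0 for c in counts):
            raise ValueError("negative count in report")
        if self.n_more_accessible > self.n_scored_regions:
            raise ValueError("more-accessible regions exceed scored regions")
        if self.n_mutant_exclusive > self.n_peaks_mutant:
            raise ValueError("exclusive regions exceed mutant peaks")
        if self.n_de_colocated_regions is not None and \
                self.n_de_colocated_regions > self.n_more_accessible:
            raise ValueError("DE-co-located regions exceed more-accessible")

    def to_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items()
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True,
                       default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_reads(paths: Sequence[str]) -> List[GenomeInterval]:
    reads: List[GenomeInterval] = []
    for path in paths:
        reads.extend(aio.read_intervals(path))
    return reads


def _as_list(value) -> List[str]:
    if value is None:
        return []
    if isinstance(value, (str, Path)):
        return [str(value)]
    return [str(v) for v in value]


def run_pipeline(
    manifest: Dict[str, object],
    config: PipelineConfig,
    outdir,
) -> AnalysisReport:
    """Run the full analysis described by a manifest of input paths.

    Mandatory manifest keys: ``reads_mutant``, ``reads_control`` (each one
    path or a list of replicate paths), ``genes``, ``chrom_sizes``.
    Optional: ``blacklist``, ``k27_reads``, ``k27_input``, ``tf_reads``,
    ``de_table``, ``signatures``.
    """
    missing = [k for k in MANDATORY if not manifest.get(k)]
    if missing:
        raise InputError(f"manifest missing mandatory inputs: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(config=config.to_dict())

    sizes = aio.read_chrom_sizes(manifest["chrom_sizes"])
    genes = aio.read_gene_models(manifest["genes"])
    blacklist = (aio.read_intervals(manifest["blacklist"])
                 if manifest.get("blacklist") else [])
    blacklist_bases = IntervalSet(blacklist).total_bases()
    eff_len = pk.effective_genome_length(
        sizes, config.excluded_chroms, blacklist_bases)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # --- filter + aggregate + pileup + call, per condition ----------------
    peak_sets: Dict[str, List[pk.Peak]] = {}
    tracks = {}
    for cond, key in (("mutant", "reads_mutant"), ("control", "reads_control")):
        reads = stage("read_input", _load_reads, _as_list(manifest[key]))
        kept, removed = stage(
            "filter", aio.filter_excluded, reads, blacklist,
            config.excluded_chroms)
        log.info("%s: %d reads, %d removed by blacklist/chrom filter",
                 cond, len(reads), removed)
        setattr(report, f"n_reads_{cond}", len(reads))
        setattr(report, f"n_filtered_{cond}", removed)
        track = stage("pileup", pk.insertion_pileup, kept, config.shift,
                      config.extsize, sizes, config.binsize)
        tracks[cond] = track
        called = stage(
            "call_peaks", pk.call_narrow_peaks, track, sizes,
            qcut=config.qcut, local_window=config.local_window,
            min_len=config.min_peak_len, effective_length=eff_len,
            blacklist=blacklist)
        peak_sets[cond] = called
        setattr(report, f"n_peaks_{cond}", len(called))
        log.info("%s: %d peaks", cond, len(called))
        path = outdir / f"peaks_{cond}.narrowPeak"
        aio.write_intervals([p.interval() for p in called], "narrowPeak", path)
        report.outputs[f"peaks_{cond}"] = path.name

    mut_set = IntervalSet(p.interval() for p in peak_sets["mutant"])
    ctrl_set = IntervalSet(p.interval() for p in peak_sets["control"])

    # --- overlap stats and exclusive regions ------------------------------
    stats = stage("overlap_stats", mut_set.overlap_stats, ctrl_set)
    report.pct_mutant_in_control = stats["pct_a_in_b"]
    report.jaccard_bp = stats["jaccard_bp"]
    report.pct_control_in_mutant = ctrl_set.overlap_stats(mut_set)["pct_a_in_b"]
    exclusive = stage("exclusive", diffacc.mutant_exclusive_regions,
                      mut_set, ctrl_set)
    report.n_mutant_exclusive = len(exclusive)
    path = outdir / "mutant_exclusive.bed"
    aio.write_intervals(exclusive.to_list(), "BED", path)
    report.outputs["mutant_exclusive"] = path.name

    # --- differential scoring over the mutant peak set --------------------
    mut_norm, ctrl_norm = stage("depth_normalize", diffacc.depth_normalize,
                                tracks["mutant"], tracks["control"])
    ratio = stage("log2_ratio", diffacc.log2_ratio_track, mut_norm, ctrl_norm,
                  config.pseudocount)
    path = outdir / "log2_ratio.bedGraph"
    aio.write_track(ratio, sizes, path)
    report.outputs["log2_ratio"] = path.name
    scored = stage("region_scores", diffacc.region_sum_scores, ratio, mut_set)
    report.n_scored_regions = len(scored)
    more = stage("select_more_accessible", diffacc.select_more_accessible,
                 scored, config.score_threshold)
    less = diffacc.flag_less_accessible(scored)
    report.n_more_accessible = len(more)
    report.n_less_accessible_flagged = len(less)
    log.info("scored %d regions; %d more accessible at tau=%g",
             len(scored), len(more), config.score_threshold)
    scored_df = pd.DataFrame({
        "chrom": [sr.region.chrom for sr in scored],
        "start": [sr.region.start for sr in scored],
        "end": [sr.region.end for sr in scored],
        "region": [sr.region.name for sr in scored],
        "log2_sum_score": [sr.score for sr in scored],
    })
    path = outdir / "scored_regions.tsv"
    scored_df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    report.outputs["scored_regions"] = path.name
    more_ivs = [sr.region for sr in more]
    path = outdir / "more_accessible.bed"
    aio.write_intervals(
        [GenomeInterval(iv.chrom, iv.start, iv.end, name=iv.name,
                        score=round(sr.score, 4))
         for iv, sr in zip(more_ivs, more)], "BED", path)
    report.outputs["more_accessible"] = path.name

    # --- genomic distributions --------------------------------------------
    dist_targets = {"all_regions": mut_set.to_list(),
                    "more_accessible": more_ivs}
    for label, regions in dist_targets.items():
        if not regions:
            continue
        table = stage("genomic_distribution", annotate.genomic_distribution,
                      regions, genes, sizes, config.promoter_window)
        report.distributions[label] = table.to_dict("records")
        path = outdir / f"distribution_{label}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        report.outputs[f"distribution_{label}"] = path.name

    # --- gene linking ------------------------------------------------------
    links = stage("link_genes", annotate.link_genes, more_ivs, genes,
                  config.gene_window, sizes)
    links_df = pd.DataFrame({
        "chrom": [l.region.chrom for l in links],
        "start": [l.region.start for l in links],
        "end": [l.region.end for l in links],
        "region": [l.region.name for l in links],
        "gene_id": [l.gene_id for l in links],
        "distance": [l.distance for l in links],
    })
    path = outdir / "gene_links.tsv"
    links_df.to_csv(path, sep="\t", index=False)
    report.outputs["gene_links"] = path.name

    # --- DE co-location ----------------------------------------------------
    de = None
    if manifest.get("de_table"):
        de = aio.read_de_table(manifest["de_table"])
        region_hits, pair_table = stage(
            "colocate_de", annotate.colocate_de, more, de, genes,
            config.gene_window, sizes)
        report.n_de_colocated_regions = len(region_hits)
        report.n_de_colocated_genes = pair_table["gene_id"].nunique() \
            if not pair_table.empty else 0
        path = outdir / "de_colocated.tsv"
        pair_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        report.outputs["de_colocated"] = path.name

    # --- chromatin-mark co-location ----------------------------------------
    k27_domains = None
    if manifest.get("k27_reads"):
        k27_reads, _ = aio.filter_excluded(
            _load_reads(_as_list(manifest["k27_reads"])), blacklist,
            config.excluded_chroms)
        k27_track = pk.insertion_pileup(k27_reads, 0, config.extsize, sizes,
                                        config.binsize)
        control_track = None
        if manifest.get("k27_input"):
            input_reads, _ = aio.filter_excluded(
                _load_reads(_as_list(manifest["k27_input"])), blacklist,
                config.excluded_chroms)
            control_track = pk.insertion_pileup(
                input_reads, 0, config.extsize, sizes, config.binsize)
        k27_domains = stage(
            "call_broad_domains", pk.call_broad_domains, k27_track, sizes,
            qcut=config.qcut, broad_cutoff=config.broad_cutoff,
            link_gap=config.effective_link_gap,
            local_window=config.local_window, effective_length=eff_len,
            control=control_track)
        report.n_k27_domains = len(k27_domains)
        path = outdir / "k27_domains.broadPeak"
        aio.write_intervals([d.interval() for d in k27_domains],
                            "broadPeak", path)
        report.outputs["k27_domains"] = path.name
        hits = stage("colocate_k27", annotate.colocate_marks, more_ivs,
                     k27_domains)
        report.n_k27_colocated = len(hits)
        _write_colocation(hits, outdir / "k27_colocated.tsv")
        report.outputs["k27_colocated"] = "k27_colocated.tsv"

    if manifest.get("tf_reads"):
        tf_reads, _ = aio.filter_excluded(
            _load_reads(_as_list(manifest["tf_reads"])), blacklist,
            config.excluded_chroms)
        tf_track = pk.insertion_pileup(tf_reads, 0, config.extsize, sizes,
                                       config.binsize)
        tf_peaks = stage("call_tf_peaks", pk.call_narrow_peaks, tf_track,
                         sizes, qcut=config.qcut,
                         local_window=config.local_window,
                         effective_length=eff_len, blacklist=blacklist)
        report.n_tf_peaks = len(tf_peaks)
        path = outdir / "tf_peaks.narrowPeak"
        aio.write_intervals([p.interval() for p in tf_peaks],
                            "narrowPeak", path)
        report.outputs["tf_peaks"] = path.name
        hits = stage("colocate_tf", annotate.colocate_marks, more_ivs,
                     [p.interval() for p in tf_peaks])
        report.n_tf_colocated = len(hits)
        _write_colocation(hits, outdir / "tf_colocated.tsv")
        report.outputs["tf_colocated"] = "tf_colocated.tsv"

    # --- signature overlap and gene-set enrichment --------------------------
    if de is not None and manifest.get("signatures"):
        signatures = aio.read_gmt(manifest["signatures"])
        universe = {g.gene_id for g in genes}
        de_genes = set(de["gene_id"]) & universe
        if de_genes and signatures:
            first = sorted(signatures)[0] if "multilineage" not in signatures \
                else "multilineage"
            overlap = stage(
                "signature_overlap", annotate.signature_overlap,
                de_genes, set(signatures[first]) & universe, universe)
            overlap["signature"] = first
            report.signature_overlap = overlap
            enrich = stage("geneset_enrichment", annotate.geneset_enrichment,
                           de_genes, {k: set(v) & universe
                                      for k, v in signatures.items()},
                           universe)
            path = outdir / "geneset_enrichment.tsv"
            enrich.to_csv(path, sep="\t", index=False, float_format="%.6g")
            report.outputs["geneset_enrichment"] = path.name

    # --- coverage matrices --------------------------------------------------
    if more_ivs:
        mat, order, offsets = stage(
            "coverage_matrix", annotate.coverage_matrix, ratio, more_ivs,
            "center", 1_000, 40, [sr.score for sr in more])
        _write_matrix(mat, order, offsets, more_ivs,
                      outdir / "matrix_log2_ratio.tsv")
        report.outputs["matrix_log2_ratio"] = "matrix_log2_ratio.tsv"
        if k27_domains is not None:
            k27_norm = k27_track.scaled(1e6 / max(k27_track.total_signal, 1),
                                        kind="normalized")
            mat, order, offsets = annotate.coverage_matrix(
                k27_norm, more_ivs, "center", 2_000, 40,
                [sr.score for sr in more])
            _write_matrix(mat, order, offsets, more_ivs,
                          outdir / "matrix_k27.tsv")
            report.outputs["matrix_k27"] = "matrix_k27.tsv"

    report.validate()
    report.to_json(outdir / "report.json")
    report.outputs["report"] = "report.json"
    (outdir / "manifest.json").write_text(json.dumps(
        {k: _as_list(manifest.get(k)) if k in ("reads_mutant", "reads_control",
                                               "k27_reads", "k27_input",
                                               "tf_reads")
         else str(manifest.get(k)) for k in MANDATORY + OPTIONAL
         if manifest.get(k)},
        indent=1, sort_keys=True))
    (outdir / "summary.txt").write_text(summarize(report))
    return report


def _write_colocation(hits, path) -> None:
    df = pd.DataFrame({
        "chrom": [iv.chrom for iv, _ in hits],
        "start": [iv.start for iv, _ in hits],
        "end": [iv.end for iv, _ in hits],
        "region": [iv.name for iv, _ in hits],
        "overlap_bp": [bp for _, bp in hits],
    })
    df.to_csv(path, sep="\t", index=False)


def _write_matrix(mat, order, offsets, regions, path) -> None:
    header = ["region"] + [f"{off:g}" for off in offsets]
    lines = ["\t".join(header)]
    for row, i in enumerate(order):
        iv = regions[i]
        label = f"{iv.chrom}:{iv.start}-{iv.end}"
        lines.append("\t".join(
            [label] + [f"{v:.6g}" for v in mat[row]]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def summarize(report: AnalysisReport) -> str:
    """One line per headline quantity, echoing the key parameters."""
    cfg = report.config
    na = "not run"

    def opt(v, fmt="{}"):
        return na if v is None else fmt.format(v)

    lines = [
        "differential accessibility summary",
        f"parameters: tau={cfg['score_threshold']} w={cfg['gene_window']} "
        f"psi={cfg['pseudocount']} binsize={cfg['binsize']} "
        f"shift={cfg['shift']} extsize={cfg['extsize']}",
        f"peaks (mutant): {report.n_peaks_mutant}",
        f"peaks (control): {report.n_peaks_control}",
        f"mutant peaks overlapping control: "
        f"{report.pct_mutant_in_control:.1f}%",
        f"mutant-exclusive regions: {report.n_mutant_exclusive}",
        f"more-accessible regions (score >= {cfg['score_threshold']}): "
        f"{report.n_more_accessible}",
        f"DE-co-located regions: {opt(report.n_de_colocated_regions)}",
        f"H3K27me3-co-located regions: {opt(report.n_k27_colocated)}",
        f"TF-co-located regions: {opt(report.n_tf_colocated)}",
        "signature overlap: " + (
            na if report.signature_overlap is None else
            "{n_overlap}/{n_a} ({pct:.0f}%) p={p_value:.3g}".format(
                pct=100 * report.signature_overlap["fraction_of_a"],
                **report.signature_overlap)),
    ]
    return "".join(line + "\n" for line in lines)
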