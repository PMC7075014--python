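# Methods

## The model

The pipeline treats ATAC-seq as a point process of Tn5 insertion events.
A fragment's 5′ end (start on `+`, end−1 on `-`) is its cut site; each cut
contributes unit coverage to `[t + shift, t + shift + extsize)`, clipped to
the chromosome. With the defaults `shift = -100`, `extsize = 200` this is a
200 bp window centred on the cut, so the pileup is a kernel-smoothed
insertion density. Coverage is accumulated on a fixed grid (`binsize` 50 bp;
a bin's value is covered bases / binsize, so total signal × binsize equals
the exact covered-base count — mass conservation is asserted in the tests).

**Peak significance.** Each bin's value k is tested against
`p = P(Poisson(λ_local) ≥ ⌈k⌉)` with
`λ_local = max(λ_genome, λ_window)`: `λ_genome` is total signal × binsize /
effective genome length (total chromosome length minus excluded chromosomes
and blacklist bases), and `λ_window` is the mean over a ±5 kb window
(`local_window` 10 kb), taken from the track itself in no-control mode or
from a depth-scaled input track when one is given. This is a deliberate
two-scale simplification of the multi-scale local-lambda idea used by
standard callers; accessibility data have no input sample, so the
self-derived window keeps narrow peaks callable while absorbing broad
coverage drifts. Rounding k up makes the discrete test conservative: on
homogeneous-Poisson input the per-bin type-I error at α is measured at
roughly α/2 (acceptance suite, 10⁵ bins). p-values are BH-adjusted across
all bins of all chromosomes jointly, which makes calls invariant to
chromosome processing order; tails that underflow are clamped to 1e-300.
Contiguous bins with q ≤ `qcut` (0.05) become a peak; the summit is the
centre of the highest-pileup bin (leftmost on ties).

**Broad domains.** Runs of bins with q ≤ `broad_cutoff` (0.1) are kept when
they contain at least one strong bin (q ≤ `qcut`) and linked across gaps up
to `link_gap` (default 4 bins = 200 bp, configurable); the domain q-value is
its best bin. A weak-only run is never a domain. With a matched input, the
window lambda comes from the input scaled by the treatment/input signal
ratio, so enrichment shared with the input is not called.

**Differential score.** Both raw pileups are scaled to equal total signal
(signal-per-million), a per-bin `log2((mut + ψ)/(ctrl + ψ))` track is formed
with ψ = 1, and each region of the *test-condition* peak set gets the sum of
the full value of every ratio bin it overlaps by ≥ 1 bp — exactly
`bedtools map -o sum` on a binned track, with no length weighting, so scores
are additive over bin-aligned partitions and antisymmetric under condition
swap. Scores scale ≈ (per-bin log2 effect) × (overlapped bin count); the
fixed threshold τ = 15 therefore implies both a substantial effect and a
minimum extent (≥ ~8 bins at effect 2). Scoring over the test-condition
peak set (not the union) matches the intended use: ranking the regions the
low-input condition did detect. Negative-score regions are flagged
`sensitivity_confounded` rather than thresholded, since lost signal in the
shallow condition is indistinguishable from lost assay sensitivity.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| shift / extsize | −100 / 200 | bp | cut-site smoothing window |
| binsize | 50 | bp | grid for pileup and ratio (shared, so no resampling) |
| pseudocount ψ | 1.0 | signal-per-million units | ratio regularisation |
| score threshold τ | 15 | dimensionless | more-accessible cutoff |
| gene window w | 10 000 | bp | region↔gene linking reach |
| promoter window | ±1 000 | bp of TSS | feature classification |
| qcut / broad_cutoff | 0.05 / 0.1 | FDR | strong / weak bin calls |
| local_window | 10 000 | bp | local lambda scale |
| link_gap | 4 × binsize | bp | broad-domain gap linking |

ψ, binsize, the promoter window and link_gap are conventional choices where
the upstream analysis protocol leaves the value open; each is a single
config field and is echoed into every report.

Feature classification uses the priority promoter > 5′UTR > 3′UTR > exon >
intron > distal intergenic; UTRs are the exonic parts outside the CDS, so
gene models without a CDS contribute exon/intron only. The genome baseline
column classifies every base by the same priority (verified against a
per-base oracle). Gene linking by ±w region extension is provably identical
to ±w gene extension; under half-open semantics a region exactly w bp from
a gene span is bookended after extension and therefore *not* linked.
Gene-set statistics are exact hypergeometric upper tails (verified against
combinatorial enumeration to 1e−12) with BH adjustment across the library.

## The synthetic generator

The generator emulates the targeted study design: two conditions sampled as
Poisson cut processes on a toy genome (default 2 × 1 Mb, 200 multi-exon
genes on both strands), with planted accessible regions of three kinds —
*shared* (equal elevated rate), *mutant-only* (elevated in the test
condition, background in control) and *fold-changed* (elevated in both,
extra 2^δ in the test condition, δ = 2) — plus blacklist artifact regions
with inflated signal in both conditions, multi-kb broad-mark domains over
half the fold-changed regions, ≤ 300 bp TF peaks at promoter-planted
regions, and a DE table in which genes near fold-changed/mutant-only
regions are up-regulated, with a "multilineage" signature built to overlap
the DE genes at 30 %.

Default scale: background 0.002 cuts/bp per unit depth with per-condition
depth 5 (the aggregate of several replicates, as such designs pool them),
planted open-chromatin enrichment 10× background, fold-changed region
length 400–800 bp, 20 regions per category, minimum 5 kb separation. The
region length and depth were sized analytically so that expected log2-sum
scores of planted fold-changes clear τ = 15 with several noise standard
deviations to spare: a region of length L overlaps ≈ (L + extsize)/binsize
+ 1 ratio bins, each contributing ≈ δ minus a depth-normalization crosstalk
term (≈ 0.2–0.3 here, because the planted test-condition excess is a
non-negligible share of a 2 Mb genome's total signal), with score noise
governed by the region's total fragment counts. At 200–400 bp the expected
score sits *at* the threshold and selection becomes a coin flip; at
400–800 bp it clears it decisively. A `depth_asymmetry` toggle sets the
test-condition depth to control/25, emulating a ~1 000-cell versus
~25 000-cell design; the depth-asymmetry acceptance experiment instead uses
a deeper dedicated configuration (background 0.05 cuts/bp, shared-only
regions with graded enrichments 3–24×) so that a 1/25 subsample still has
callable peaks and the peak-set containment comparison is informative.

Everything is a pure function of (config, seed); fixtures are byte-stable.
What the generator does **not** model: Tn5 sequence bias, nucleosomal
fragment-length periodicity, GC bias, replicate-level biological variance,
mappability structure. Passing tests therefore demonstrate the pipeline's
statistical and set-algebra correctness under its stated model, not
robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

- Ties in sorting break by (start, end, name); summit ties leftmost —
  everything is deterministic, and re-running the pipeline is byte-identical
  (output paths in reports are directory-relative for this reason).
- A zero-signal track yields all p = 1 (no calls) rather than an error in
  the callers; depth normalization of a zero-signal track is an error.
- bedGraph resampling is a length-weighted mean with uncovered bases = 0;
  the last, possibly partial, bin of a chromosome is weighted by the bases
  it actually contains.
- Coverage-matrix windows are real-valued intervals over the
  piecewise-constant track, so row means are exactly invariant to window
  refinement; bases beyond the chromosome count as 0 with the full window
  length as denominator.
- Blacklist filtering is applied to reads before pileup *and* to called
  peaks, each step logged with counts.

## Problem sizes

The test suite and the acceptance script run the full design at the default
2 Mb / ~60-region scale (seconds per run), the null calibration on a 5 Mb
chromosome (10⁵ bins, five seeds), and oracle comparisons on 500–1 000
randomized instances with coordinates below 10⁵ — sizes chosen so the whole
suite completes in about half a minute while keeping every Monte-Carlo
margin wide.

## Known limitations

- The two-scale local lambda is simpler than production callers'
  multi-scale scheme; very broad accessibility gradients can locally raise
  λ and suppress wide weak peaks in no-control mode.
- Region scores have no replicate-aware error model; τ is a fixed empirical
  threshold by design, and no FDR is attached to region selection.
- Fractional-overlap co-location criteria are not implemented; any ≥ 1 bp
  overlap co-locates, matching default `bedtools intersect`.
- BED12/BED6 are the only gene-model inputs; BAM/CRAM and bigWig are out of
  scope (fragment BED and bedGraph are the canonical interchange formats).
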