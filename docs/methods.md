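# Methods

## Coordinate conventions

All coordinates are 0-based half-open `[start, end)` on ingest: BED and
bedGraph are adopted verbatim, fixed-step wiggle starts are shifted by one.
Coverage tracks store one value per base; positions outside the covered
range score 0, matching read-pileup semantics. The center of an interval is
`floor((start+end)/2)`; for even-length loci this deterministic floor
tie-break keeps all window arithmetic integral.

## Classification

**Positional.** A locus is *exonic* if it overlaps any exon by ≥ 1 bp —
any exon overlap means the locus is partly exonic sequence, so exon
overlap takes precedence over intron containment. Otherwise it is
*intronic* if fully contained in an intron (host gene and intron recorded;
when several genes could host it, the first in (start, name) order wins —
a deterministic tie-break that does not affect the class), else
*intergenic*. Introns are derived as the gaps between consecutive exons of
each gene model.

**Expression.** *Expressed* iff the read count is positive; ids absent
from the expression table count as zero reads.

**Promoter.** The search region is the 250,000 nt upstream of the locus,
strand-aware (5′ of the locus on its annotated strand; unstranded loci
default to the + convention with a warning). The promoter is *active* iff
calls of all three marks (RNAPII, H3K4me3, H2A.Z) fall in the region and
either an RNAPII call co-localizes with an H2A.Z and/or H3K4me3 call, or
an H3K4me3 call co-localizes with an H2A.Z call. Co-localization means
≥ 1 bp overlap of the call intervals after clipping to the search region;
`colocalize_max_gap` (default 0) relaxes this to a bp distance when
positive. A non-active locus is *inactive* if unexpressed, otherwise
*unidentified*. The three axes are independent labels, not a partition,
but each axis itself is deterministic and exhaustive.

## Metaprofiles

Each locus contributes the 2,000-nt window around its center; minus-strand
loci are flipped so downstream = plus in transcript orientation
(`strand_flip=False` restores genomic orientation). Each 10-nt sliding
window is assigned the mean of the per-base scores in the 140 nt centered
on it (65 nt on each side of the 10-nt window); at the vector edges the
neighborhood is truncated and the mean is taken over the available
positions only — no data is fabricated beyond the window. Smoothing is a
boxcar mean, hence linear; the implementation is a cumulative-sum
difference and is checked against an independent nested-loop oracle to
1e-12. Window offsets are reported at the continuous midpoints
(−995, −985, …, +995), symmetric about the locus center.

Sequence content at position *i* is *N*/*T* over the 100-nt window
`[i−50, i+50)`: mononucleotide patterns count G/C (or A/T) over all
unambiguous bases; dinucleotide patterns count overlapping 2-mers in
{GC, CG} (or {AT, TA}) over all fully unambiguous 2-mers, attributing each
2-mer to its first base. Ambiguous bases are excluded from both *N* and
*T*; a window with *T* = 0 yields NaN, and metaprofile means are NaN-aware.
Content is always computed on the + genome strand: GC/AT content is
strand-symmetric and both dinucleotide sets are reverse-complement closed,
so the choice is consequence-free (asserted by test). Whether "GC
dinucleotides" means {GC, CG} or CpG only is a genuine ambiguity; {GC, CG}
is the default and the pattern set is explicit in the API.

## Control windows

The center window is `[center−1000, center+1000)`. Flanks by class:

* **intronic** — full 2,000-nt windows tiled outward from both
  center-window boundaries, stopping at the host intron's splice sites;
  partial windows are discarded. Tiling is anchored at the center-window
  boundary (not the intron boundary) so the window nearest the locus is
  always full-width. The emitted count per side equals
  `max(0, floor(room/2000))` where room is the distance from the
  center-window boundary to the intron boundary.
* **intergenic / exonic** — the two windows immediately adjacent to the
  center window. "Adjacent" is the minimal-distance reading of a flanking
  window; `flank_gap` inserts an explicit gap for sensitivity analysis.
  Exonic flanks may extend past the host exon; no trimming is applied.

Windows crossing chromosome ends are dropped, and loci whose center
window would cross are excluded and counted. The paired score per locus is
(center core mean, aggregate of flank core means), where a core mean is
the arithmetic mean over the 400-nt window around a window's midpoint and
the flank aggregate is the unweighted mean (median available via
`flank_agg`). Flanks are deliberately not matched on GC or mappability and
flanks overlapping neighboring genes are not excluded — the comparison
characterises the locus against its immediate genomic neighborhood as-is.

## Statistics

Paired center-vs-flank comparisons use the Wilcoxon signed-rank test:
zero differences dropped (classic convention), midranks for ties,
statistic W⁺ = sum of ranks of positive differences. The p-value is the
exact enumeration value for tie-free samples with n ≤ 25 and otherwise
the normal approximation with tie and continuity corrections. Unpaired
group-vs-group comparisons use the Mann–Whitney rank-sum test (exact for
tie-free n+m ≤ 12, otherwise corrected normal approximation). A paired
signed-rank test is impossible between groups of unequal size, so
unpaired contrasts are always rank-sum here. Occupancy–expression
association uses Kendall's tau-b with the asymptotic normal p-value.
p-values come from scipy.stats behind this regime selection and are
reported as computed, without any reporting floor. No multiple-testing
correction is applied. Degenerate inputs: all-zero differences give
p = 1 with a warning; zero-variance input to tau is an error.

GC-quintile binning scores each locus by the GC fraction of its 400-nt
core window, sorts ascending (ties broken by id so membership is
input-order invariant) and splits into five contiguous bins whose sizes
differ by at most one, remainder to the lowest-GC bins. Occupancy density
is feature signal sum divided by feature length. The occupancy histogram
bins core-window means with a right-closed final bin so percentages sum
to 100 when all scores are in range.

## Synthetic data

The generator emulates the assumed data structure: ~80-nt loci (pre-miRNA
hairpins average roughly 70–110 nt) placed in cassettes — a two-exon gene
(300-nt exons, 7,000-nt intron) hosting an intron-centered locus; a
single-exon 400-nt gene containing an exonic locus; a bare intergenic
locus — separated by 4,000-nt gaps so every locus has room for its center
window and two flanks. Sequence is i.i.d. at background GC 0.40
(human-like); each locus is resampled at background + 0.12, matching the
reported elevation of pre-miRNA GC over flanking sequence (an optional
two-peak variant raises GC in the two stem arms only). Occupancy per base
is

```
b0 + beta_GC * GC100(i) + sum_c A * exp(-(i-c)^2 / (2 hw^2)) + eps,  eps ~ N(0, sigma) truncated at 0
```

with defaults b0 = 1.0, beta_GC = 1.0, A = 0.8, hw = 75 nt,
sigma = 0.25 — a clearly visible but noisy central enrichment of roughly
nucleosome half-width. The Gaussian kernel is a shape-agnostic choice for
a central peak; `kernel="box:147"` substitutes a single-nucleosome
boxcar footprint. Truncation at 0 keeps tracks valid coverage and
introduces a slight positive bias only when b0 is small relative to
sigma. Mark/RNAPII tracks use the same form with amplitude 0.6 applied
only at loci designated active or expressed. Expression is zero-inflated
(pi0 = 0.3) log-normal (mu = 3, s = 1.2) rounded to read counts;
expression and occupancy are generated independently, so the measured
occupancy–expression tau fluctuates around 0. Promoter calls (RNAPII
500 nt, H3K4me3 500 nt, H2A.Z 300 nt, mutually overlapping) are planted
~5 kb upstream of each designated-active locus.

`truth.tsv` records the planted classes. Positional and expression truths
are pure plants. Promoter truth cannot be: calls planted for one locus can
fall within another locus's 250-kb search window, so the truth records the
deterministic consequence of the full planted call set under the
co-localization rule, computed by an independent re-implementation of the
rule inside the generator (not the classify module), keeping
truth-vs-pipeline comparisons a genuine dual-route check.

What the generator does **not** emulate: read-level sampling noise and
mappability structure, sequence-dependent nucleosome positioning
preferences, correlated noise along the genome, realistic gene
architecture (exon/intron length distributions), or any coupling between
expression level and chromatin signal beyond the binary active/expressed
designation. Passing tests therefore demonstrate correctness of the
pipeline's computations and calibration of its statistics under the
assumed signal model — not biological conclusions about real chromatin.

`replicate_runner` reruns generate → classify → windows → compare with
seed = base + replicate index. Calibration studies use an intergenic-only
design (100 loci, 420-kb chromosome, no marks, all loci unexpressed) so
each locus contributes exactly one (center, flank-mean) pair; the null
configuration sets both A = 0 and beta_GC = 0, since GC coupling combined
with the planted locus GC elevation is itself an enrichment. At these
sizes the type-I rate at alpha = 0.05 over 500 replicates sits inside the
exact binomial 99% interval, and with A = 3 sigma the paired p-value is
below 1e-4 in every replicate.

## Problem sizes

Default bundle: one 1.2-Mb chromosome, 125 loci (50 intronic / 50
intergenic / 25 exonic). Calibration: 100-locus intergenic design, 500
null replicates in tests (200 in the acceptance script, plus 100 and 60
power replicates respectively). These sizes give stable Monte-Carlo
estimates while keeping a full test run under a minute of compute for the
simulation-heavy parts.

## Known limitations

* bedGraph/wiggle only; bigWig (binary) is out of scope.
* The refGene reader requires a header line naming the six columns it
  uses; headerless UCSC dumps need a header prepended.
* Exact rank-test enumeration thresholds (n ≤ 25 paired, n+m ≤ 12
  unpaired, tie-free) are fixed conventions, not data-adaptive choices.
* Report tables are TSV + JSON manifest; no figure rendering.
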