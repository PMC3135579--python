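# mirchrom

Chromatin profiling of pre-miRNA genomic sequences.

Pre-miRNAs are ~70–110-nt hairpin precursors excised co-transcriptionally
from primary miRNA transcripts. Their genomic sequences sit in distinctive
chromatin: nucleosome occupancy is locally enriched over the hairpin, the
enrichment tracks GC content, and elongation-associated histone marks and
RNA Polymerase II are elevated over loci whose miRNAs are transcribed.
`mirchrom` is a reusable, tested pipeline for quantifying these effects.
It is written for computational epigenomics work: given pre-miRNA
annotations, gene models, per-base signal tracks, promoter-mark enrichment
calls, a genome and a mature-miRNA expression table, it

1. **classifies** every pre-miRNA along three independent axes —
   positional (*intronic* / *intergenic* / *exonic* by overlap with gene
   models), expression (*expressed* iff deep-sequencing reads > 0), and
   promoter (*active* / *inactive* / *unidentified* via co-localization of
   RNAPII, H3K4me3 and H2A.Z enrichment calls in the 250-kb upstream
   region);
2. **profiles** signal in 2,000-nt windows aligned on locus centers
   (position 0 = center, downstream = plus), smoothing each 10-nt sliding
   window with the mean of the surrounding 140 nt, and computes windowed
   GC / AT / dinucleotide content, where the content of a sequence *S* is
   *N*/*T* (*N* = matching nucleotides or 2-mers, *T* = total counted);
3. **builds flanking control windows** — tiled across the host intron for
   intronic loci, the two adjacent 2,000-nt windows otherwise — and
   compares the 400-nt core occupancy of center vs flank with the
   Wilcoxon signed-rank test;
4. runs the rest of the **statistical battery**: Mann–Whitney rank-sum
   for unpaired group comparisons, Kendall's tau-b for
   occupancy–expression association, GC-quintile binning,
   length-normalised occupancy densities for pre-miRNAs / exons /
   introns, and occupancy histograms.

A fully synthetic data generator (`mirchrom.synthdata`) produces
genome + annotation + track + expression bundles with planted effects —
GC-elevated loci, a Gaussian occupancy enrichment at each locus center,
occupancy coupled to local GC, marks elevated at active/expressed loci —
so the entire pipeline is testable without any external downloads.

## Worked example

```python
from mirchrom import SyntheticConfig, generate_bundle, annotate, center_vs_flank
from mirchrom.classify import EnrichmentCall

bundle = generate_bundle(SyntheticConfig(seed=1))   # 50 intronic / 50 intergenic / 25 exonic loci
calls = [EnrichmentCall(m, iv) for m, iv in bundle.calls]
ann = annotate(bundle.loci, bundle.genes, bundle.expression, calls)
print(sum(a.positional_class == "intronic" for a in ann), "intronic loci")

res = center_vs_flank(bundle)
print(f"W+ = {res.statistic:.0f}, p = {res.p_value:.3g}, n = {res.n}")
```

prints

```
50 intronic loci
W+ = 7875, p = 3e-22, n = 125
```

All 50 planted intronic loci are recovered, and the paired signed-rank
test detects the planted central occupancy enrichment (center core mean
vs mean of flank core means over 125 loci): W⁺ = 7875 is the maximum
possible rank sum — every locus scores higher at its center than in its
flanks — giving p ≈ 3×10⁻²².

The same study runs from the shell:

```bash
mirchrom simulate --seed 1 -o bundle/
mirchrom classify --bed bundle/mirna.bed --genes bundle/genes.tsv \
    --expr bundle/expr.tsv --calls bundle/calls.bed -o annotations.tsv
mirchrom windows  --bed bundle/mirna.bed --genes bundle/genes.tsv \
    --expr bundle/expr.tsv --calls bundle/calls.bed -o windows.bed
mirchrom compare  --windows-bed windows.bed --track bundle/occupancy.bedGraph -o cmp.tsv
```

`mirchrom run --config run.json` executes the full study (annotation
table, per-group metaprofiles, content profiles, GC-quintile profiles,
all rank tests, density distributions, occupancy histogram) and writes
plain TSV tables plus a JSON manifest.

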