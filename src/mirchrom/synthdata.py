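"""Synthetic genome / annotation / track bundles with planted structure.

The generator emulates the statistical structure the analysis assumes:

* pre-miRNA-sized loci (default 80 nt) embedded in introns, in exons and
  in intergenic space, each cassette separated by enough clearance for a
  2,000-nt center window plus flanks;
* genome sequence drawn i.i.d. at a background GC fraction, with each
  locus resampled at an elevated GC fraction;
* a nucleosome-occupancy track
  ``b0 + beta_gc * GC100(i) + sum_c A * exp(-(i-c)^2 / (2 hw^2)) + noise``
  with a Gaussian enrichment kernel at every locus center and truncated
  Gaussian noise (an optional 147-nt boxcar kernel echoes the footprint of
  a single nucleosome);
* histone-mark / RNAPII tracks of the same form whose enrichment amplitude
  applies only at designated active/expressed loci;
* promoter enrichment calls planted upstream of designated-active loci so
  the three-mark co-localization rule fires for them;
* a zero-inflated log-normal expression table.

``truth.tsv`` records the planted classes so pipeline output can be
checked against ground truth. Positional and expression truths are pure
plants; the promoter truth is the deterministic consequence of the planted
call set under the co-localization rule (calls planted for one locus can
fall in another locus's 250-kb search window), evaluated here by an
independent re-implementation of the rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PROMOTER_MARKS
from .errors import ValidationError
from .genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    GenomeSequence,
    write_bed,
    write_bedgraph,
    write_fasta,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MARKS = ("H2BK5me1", "H3K36me3", "H4K20me1", "RNAPII")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults reflect the study conditions the pipeline targets: ~80-nt
    loci, GC-elevated relative to background, a localized occupancy
    enrichment at locus centers, and marks elevated only at the
    active/expressed subset.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chromosome_length: int = 1_200_000
    n_intronic: int = 50
    n_intergenic: int = 50
    n_exonic: int = 25
    mirna_length: int = 80
    exon_length: int = 300
    intron_length: int = 7_000
    exonic_gene_exon_length: int = 400
    cassette_gap: int = 4_000
    baseline: float = 1.0  # b0
    gc_coupling: float = 1.0  # beta_GC
    amplitude: float = 0.8  # A
    half_width: int = 75  # hw, nt
    kernel: str = "gaussian"  # or "box:<width>"
    noise_sd: float = 0.25  # sigma
    background_gc: float = 0.40
    locus_gc_boost: float = 0.12  # delta_GC
    two_peak_gc: bool = False
    frac_active: float = 0.4
    zero_inflation: float = 0.3  # pi0
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.2
    marks: tuple[str, ...] = DEFAULT_MARKS
    mark_amplitude: float = 0.6
    include_marks: bool = True
    promoter_offset: int = 5_000  # call placement upstream of locus start
    promoter_search_span: int = 250_000

    def __post_init__(self) -> None:
        for name in ("chromosome_length", "mirna_length", "exon_length",
                     "intron_length", "exonic_gene_exon_length", "cassette_gap",
                     "half_width", "promoter_offset"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValidationError("zero_inflation must lie in [0, 1]")
        if not 0.0 <= self.frac_active <= 1.0:
            raise ValidationError("frac_active must lie in [0, 1]")
        if not 0.0 < self.background_gc < 1.0:
            raise ValidationError("background_gc must lie in (0, 1)")
        if not 0.0 <= self.background_gc + self.locus_gc_boost <= 1.0:
            raise ValidationError("background_gc + locus_gc_boost outside [0, 1]")
        if self.mirna_length >= self.intron_length - 2 * 2000:
            raise ValidationError("intron too short to host a locus with flanks")
        if self.kernel != "gaussian" and not self.kernel.startswith("box:"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")


@dataclass
class SyntheticBundle:
    """In-memory result of one generator run."""

    config: SyntheticConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    loci: list[tuple[str, GenomicInterval]]
    occupancy: CoverageTrack
    marks: dict[str, CoverageTrack]
    calls: list[tuple[str, GenomicInterval]]  # (mark, region)
    expression: dict[str, float]
    truth: pd.DataFrame

    @property
    def genome(self) -> GenomeSequence:
        return GenomeSequence(self.sequences)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, outdir) -> dict[str, Path]:
        """Serialize the bundle to plain-text files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.tsv",
            "mirna": outdir / "mirna.bed",
            "occupancy": outdir / "occupancy.bedGraph",
            "calls": outdir / "calls.bed",
            "expression": outdir / "expr.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(paths["genome"], self.sequences)
        with open(paths["genes"], "w") as fh:
            fh.write("name\tchrom\tstrand\texonCount\texonStarts\texonEnds\n")
            for g in self.genes:
                starts = ",".join(str(e.start) for e in g.exons) + ","
                ends = ",".join(str(e.end) for e in g.exons) + ","
                fh.write(
                    f"{g.name}\t{g.chrom}\t{g.strand}\t{len(g.exons)}\t{starts}\t{ends}\n"
                )
        write_bed(paths["mirna"], self.loci)
        write_bedgraph(paths["occupancy"], self.occupancy)
        markdir = outdir / "marks"
        markdir.mkdir(exist_ok=True)
        for mark, track in self.marks.items():
            p = markdir / f"{mark}.bedGraph"
            write_bedgraph(p, track)
            paths[f"mark:{mark}"] = p
        write_bed(paths["calls"], self.calls)
        with open(paths["expression"], "w") as fh:
            fh.write("mirna_id\treads\n")
            for name, _ in self.loci:
                fh.write(f"{name}\t{self.expression[name]:g}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


@dataclass
class _Cassette:
    kind: str  # intronic / intergenic / exonic
    length: int = 0
    locus_offset: int = 0  # locus start relative to cassette start
    gene_exons: list[tuple[int, int]] = field(default_factory=list)


def _plan_cassettes(cfg: SyntheticConfig) -> list[_Cassette]:
    """Cassette geometry per positional class (offsets, not genome coords)."""
    plans = []
    m = cfg.mirna_length
    intronic = _Cassette("intronic")
    intron_mid = cfg.exon_length + cfg.intron_length // 2
    intronic.locus_offset = intron_mid - m // 2
    intronic.gene_exons = [
        (0, cfg.exon_length),
        (cfg.exon_length + cfg.intron_length,
         2 * cfg.exon_length + cfg.intron_length),
    ]
    intronic.length = 2 * cfg.exon_length + cfg.intron_length
    plans.append(intronic)

    intergenic = _Cassette("intergenic", length=m, locus_offset=0)
    plans.append(intergenic)

    exonic = _Cassette("exonic")
    exonic.gene_exons = [(0, cfg.exonic_gene_exon_length)]
    exonic.locus_offset = cfg.exonic_gene_exon_length // 2 - m // 2
    exonic.length = cfg.exonic_gene_exon_length
    plans.append(exonic)
    return plans


def _layout(cfg: SyntheticConfig, rng: np.random.Generator):
    """Place cassettes on chromosomes; error out if they cannot fit."""
    plans = {p.kind: p for p in _plan_cassettes(cfg)}
    order = (
        ["intronic"] * cfg.n_intronic
        + ["intergenic"] * cfg.n_intergenic
        + ["exonic"] * cfg.n_exonic
    )
    if not order:
        raise ValidationError("no loci requested")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    placements = []  # (kind, chrom, cassette_start)
    cursor = {c: cfg.cassette_gap for c in chroms}
    ci = 0
    for kind in order:
        plan = plans[kind]
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            start = cursor[chrom]
            if start + plan.length + cfg.cassette_gap <= cfg.chromosome_length:
                placements.append((kind, chrom, start))
                cursor[chrom] = start + plan.length + cfg.cassette_gap
                ci += 1
                placed = True
                break
            ci += 1
        if not placed:
            raise ValidationError(
                "infeasible geometry: loci plus clearance exceed chromosome "
                f"capacity ({cfg.n_chromosomes} x {cfg.chromosome_length} nt)"
            )
    return plans, placements


def _sample_sequence(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=probs)


def _rolling_gc(seq_arr: np.ndarray, window: int) -> np.ndarray:
    """Per-base GC fraction over the centered ``window`` (truncated edges)."""
    is_gc = np.isin(seq_arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(is_gc)))
    idx = np.arange(seq_arr.size)
    half = window // 2
    los = np.clip(idx - half, 0, seq_arr.size)
    his = np.clip(idx + window - half, 0, seq_arr.size)
    return (csum[his] - csum[los]) / (his - los)


def _kernel_profile(cfg: SyntheticConfig, length: int, centers: list[int],
                    amplitude: float) -> np.ndarray:
    out = np.zeros(length)
    if amplitude == 0 or not centers:
        return out
    if cfg.kernel == "gaussian":
        reach = 6 * cfg.half_width
        for c in centers:
            lo, hi = max(0, c - reach), min(length, c + reach)
            x = np.arange(lo, hi) - c
            out[lo:hi] += amplitude * np.exp(-(x**2) / (2 * cfg.half_width**2))
    else:
        width = int(cfg.kernel.split(":", 1)[1])
        for c in centers:
            lo, hi = max(0, c - width // 2), min(length, c + width - width // 2)
            out[lo:hi] += amplitude
    return out


def _independent_promoter_rule(
    locus: GenomicInterval,
    calls: list[tuple[str, GenomicInterval]],
    expressed: bool,
    span: int,
) -> str:
    """Co-localization rule re-derived from first principles for truth.tsv.

    Deliberately not the classify module: keeps truth independent of the
    code under test.
    """
    if locus.strand == "-":
        u_lo, u_hi = locus.end, locus.end + span
    else:
        u_lo, u_hi = max(0, locus.start - span), locus.start
    clipped: dict[str, list[tuple[int, int]]] = {m: [] for m in PROMOTER_MARKS}
    for mark, region in calls:
        if region.chrom != locus.chrom:
            continue
        lo, hi = max(region.start, u_lo), min(region.end, u_hi)
        if lo < hi:
            clipped[mark].append((lo, hi))
    if all(clipped[m] for m in PROMOTER_MARKS):
        def meets(a, b):
            return any(x0 < y1 and y0 < x1 for x0, x1 in a for y0, y1 in b)
        rnap, k4, z = (clipped[m] for m in PROMOTER_MARKS)
        if meets(rnap, z) or meets(rnap, k4) or meets(k4, z):
            return "active"
    return "unidentified" if expressed else "inactive"


def generate_bundle(
    config: SyntheticConfig, outdir=None
) -> SyntheticBundle:
    """Generate one bundle; optionally serialize it to ``outdir``.

    Deterministic for a fixed config (seed included): re-running writes
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    plans, placements = _layout(config, rng)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seq_arrays = {
        c: _sample_sequence(rng, config.chromosome_length, config.background_gc)
        for c in chroms
    }

    genes: list[GeneModel] = []
    loci: list[tuple[str, GenomicInterval]] = []
    centers_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    kinds: list[str] = []
    counter = {"intronic": 0, "intergenic": 0, "exonic": 0}
    for kind, chrom, start in placements:
        plan = plans[kind]
        counter[kind] += 1
        idx = counter[kind]
        strand = "+" if rng.random() < 0.5 else "-"
        locus_start = start + plan.locus_offset
        locus = GenomicInterval(chrom, locus_start, locus_start + config.mirna_length, strand)
        name = f"mir-{kind}-{idx}"
        loci.append((name, locus))
        kinds.append(kind)
        centers_by_chrom[chrom].append((locus.start + locus.end) // 2)
        if plan.gene_exons:
            exons = [
                GenomicInterval(chrom, start + s, start + e, strand)
                for s, e in plan.gene_exons
            ]
            genes.append(GeneModel(f"gene-{kind}-{idx}", chrom, strand, exons))

    # resample locus sequence at elevated GC (optionally two stem peaks)
    locus_gc = config.background_gc + config.locus_gc_boost
    for name, locus in loci:
        arr = seq_arrays[locus.chrom]
        if config.two_peak_gc:
            third = config.mirna_length // 3
            arr[locus.start : locus.start + third] = _sample_sequence(
                rng, third, min(1.0, locus_gc + 0.05)
            )
            arr[locus.start + third : locus.end - third] = _sample_sequence(
                rng, locus.length - 2 * third, config.background_gc
            )
            arr[locus.end - third : locus.end] = _sample_sequence(
                rng, third, min(1.0, locus_gc + 0.05)
            )
        else:
            arr[locus.start : locus.end] = _sample_sequence(
                rng, locus.length, locus_gc
            )

    sequences = {c: a.tobytes().decode("ascii") for c, a in seq_arrays.items()}

    n = len(loci)
    expressed = rng.random(n) >= config.zero_inflation
    levels = np.where(
        expressed,
        np.maximum(
            1.0,
            np.round(
                rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)
            ),
        ),
        0.0,
    )
    active = rng.random(n) < config.frac_active
    expression = {name: float(levels[i]) for i, (name, _) in enumerate(loci)}

    # promoter calls upstream of designated-active loci (strand-aware)
    calls: list[tuple[str, GenomicInterval]] = []
    chrom_len = config.chromosome_length
    for i, (name, locus) in enumerate(loci):
        if not active[i]:
            continue
        if locus.strand == "-":
            base = locus.end + config.promoter_offset
        else:
            base = locus.start - config.promoter_offset - 700
        if base < 0 or base + 700 > chrom_len:
            base = max(0, min(base, chrom_len - 700))
        calls.append(("RNAPII", GenomicInterval(locus.chrom, base, base + 500)))
        calls.append(("H3K4me3", GenomicInterval(locus.chrom, base + 200, base + 700)))
        calls.append(("H2A.Z", GenomicInterval(locus.chrom, base + 100, base + 400)))

    # occupancy: baseline + GC coupling + enrichment kernels + noise
    occupancy = CoverageTrack()
    mark_tracks = {m: CoverageTrack() for m in config.marks} if config.include_marks else {}
    active_or_expressed = {
        loci[i][0] for i in range(n) if active[i] or expressed[i]
    }
    hot_centers: dict[str, list[int]] = {c: [] for c in chroms}
    for i, (name, locus) in enumerate(loci):
        if name in active_or_expressed:
            hot_centers[locus.chrom].append((locus.start + locus.end) // 2)
    for chrom in chroms:
        length = config.chromosome_length
        base = np.full(length, config.baseline)
        if config.gc_coupling != 0.0:
            base = base + config.gc_coupling * _rolling_gc(seq_arrays[chrom], 100)
        occ = base + _kernel_profile(
            config, length, centers_by_chrom[chrom], config.amplitude
        )
        if config.noise_sd > 0:
            occ = occ + rng.normal(0.0, config.noise_sd, size=length)
        occupancy.set_chromosome(chrom, np.maximum(occ, 0.0))
        for mark in mark_tracks:
            sig = np.full(length, config.baseline) + _kernel_profile(
                config, length, hot_centers[chrom], config.mark_amplitude
            )
            if config.noise_sd > 0:
                sig = sig + rng.normal(0.0, config.noise_sd, size=length)
            mark_tracks[mark].set_chromosome(chrom, np.maximum(sig, 0.0))

    rows = []
    for i, (name, locus) in enumerate(loci):
        promoter = _independent_promoter_rule(
            locus, calls, bool(expressed[i]), config.promoter_search_span
        )
        rows.append(
            {
                "mirna_id": name,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "strand": locus.strand,
                "positional_class": kinds[i],
                "expression_level": float(levels[i]),
                "expression_class": "expressed" if expressed[i] else "unexpressed",
                "promoter_class": promoter,
                "planted_active_calls": bool(active[i]),
            }
        )
    truth = pd.DataFrame(rows)

    bundle = SyntheticBundle(
        config=config,
        sequences=sequences,
        genes=genes,
        loci=loci,
        occupancy=occupancy,
        marks=mark_tracks,
        calls=calls,
        expression=expression,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def expected_enrichment_area(config: SyntheticConfig) -> float:
    """Area under one Gaussian enrichment kernel: A * hw * sqrt(2*pi)."""
    return config.amplitude * config.half_width * math.sqrt(2 * math.pi)


def replicate_runner(
    config: SyntheticConfig,
    n_replicates: int,
    pipeline_call=None,
) -> pd.DataFrame:
    """Run generate -> classify -> windows -> compare per replicate.

    Replicate r uses seed = config.seed + r. ``pipeline_call`` maps a
    SyntheticBundle to a StatResult; the default runs the paired
    center-vs-flank signed-rank test on the occupancy track. Returns a
    tidy DataFrame with one row per replicate.
    """
    from .pipeline import center_vs_flank  # late import: avoid cycle

    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if pipeline_call is None:
        pipeline_call = center_vs_flank
    rows = []
    for r in range(n_replicates):
        cfg = replace(config, seed=config.seed + r)
        bundle = generate_bundle(cfg)
        try:
            result = pipeline_call(bundle)
        except Exception as exc:  # annotate failures with the replicate
            raise type(exc)(f"replicate {r}: {exc}") from exc
        rows.append(
            {
                "replicate": r,
                "seed": cfg.seed,
                "method": result.method,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n": result.n,
            }
        )
    return pd.DataFrame(rows)
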