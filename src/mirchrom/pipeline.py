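"""End-to-end orchestration: classify, profile, compare, report.

``run_all`` executes the full study on one input bundle and writes plain
TSV report tables plus a JSON manifest: per-group annotation table,
center-aligned occupancy/mark metaprofiles, the four sequence-content
profiles, GC-quintile occupancy profiles, paired center-vs-flank and
group-vs-group rank tests, length-normalised density distributions, the
core-occupancy histogram and the occupancy-expression Kendall correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    EnrichmentCall,
    MiRNAAnnotation,
    annotate,
    expression_groups,
)
from .errors import DataError, ValidationError
from .genomic_io import (
    CoverageTrack,
    GenomeSequence,
    read_bed,
    read_coverage,
    read_expression_table,
    read_fasta,
    read_gene_models,
)
from .metaprofile import (
    CONTENT_PATTERNS,
    ProfileParams,
    annotation_profile,
    center_of,
    content_metaprofile,
)
from .stats import (
    StatResult,
    gc_quintile_bins,
    kendall_tau,
    occupancy_density,
    occupancy_histogram,
    rank_sum_test,
    wilcoxon_signed_rank,
)
from .windows import build_window_sets, core_mean, paired_core_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    mirna_bed: str
    genes_tsv: str
    occupancy_track: str
    fasta: str
    expression_tsv: str
    calls_bed: str
    outdir: str
    mark_tracks: dict[str, str] = field(default_factory=dict)
    params: ProfileParams = field(default_factory=ProfileParams)
    seed: int = 0
    search_span: int = 250_000
    flank_gap: int = 0
    histogram_edges: list[float] | None = None

    def validate(self) -> None:
        paths = [self.mirna_bed, self.genes_tsv, self.occupancy_track,
                 self.fasta, self.expression_tsv, self.calls_bed,
                 *self.mark_tracks.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        labels = list(self.mark_tracks)
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate track labels")


@dataclass
class StudyInputs:
    """Deserialized inputs, independent of their on-disk form."""

    loci: list
    genes: list
    occupancy: CoverageTrack
    genome: GenomeSequence
    expression: dict[str, float]
    calls: list[EnrichmentCall]
    marks: dict[str, CoverageTrack] = field(default_factory=dict)


def load_inputs(config: RunConfig) -> StudyInputs:
    config.validate()
    loci = read_bed(config.mirna_bed)
    genes = read_gene_models(config.genes_tsv)
    occupancy = read_coverage(config.occupancy_track, "bedgraph")
    genome = read_fasta(config.fasta)
    expression = {
        r.mirna_id: r.level for r in read_expression_table(config.expression_tsv)
    }
    calls = [
        EnrichmentCall(name, region) for name, region in read_bed(config.calls_bed)
    ]
    marks = {
        label: read_coverage(path, "bedgraph")
        for label, path in config.mark_tracks.items()
    }
    if not loci:
        raise DataError("no pre-miRNA loci in input BED")
    return StudyInputs(loci, genes, occupancy, genome, expression, calls, marks)


def center_vs_flank(bundle_or_inputs, params: ProfileParams = ProfileParams(),
                    annotations=None, track=None) -> StatResult:
    """Paired signed-rank test of center vs flank core occupancy.

    Accepts a SyntheticBundle (or StudyInputs) and derives annotations and
    the occupancy track from it unless given explicitly.
    """
    if annotations is None:
        src = bundle_or_inputs
        expression = src.expression
        calls = getattr(src, "calls", [])
        call_objs = [
            c if isinstance(c, EnrichmentCall) else EnrichmentCall(c[0], c[1])
            for c in calls
        ]
        annotations = annotate(src.loci, src.genes, expression, call_objs)
    if track is None:
        track = bundle_or_inputs.occupancy
    chrom_lengths = None
    if hasattr(bundle_or_inputs, "chrom_lengths"):
        chrom_lengths = bundle_or_inputs.chrom_lengths()
    window_sets, _ = build_window_sets(annotations, params,
                                       chrom_lengths=chrom_lengths)
    pairs, _ = paired_core_scores(window_sets, track, params)
    if not pairs:
        raise DataError("no features eligible for the paired comparison")
    centers = np.array([p[1] for p in pairs])
    flanks = np.array([p[2] for p in pairs])
    return wilcoxon_signed_rank(centers, flanks)


def _annotations_frame(annotations, groups) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "mirna_id": a.mirna_id,
                "chrom": a.locus.chrom,
                "start": a.locus.start,
                "end": a.locus.end,
                "strand": a.locus.strand,
                "positional_class": a.positional_class,
                "host_gene": a.host_gene or "noData",
                "expression_level": a.expression_level,
                "expression_class": a.expression_class,
                "promoter_class": a.promoter_class,
                "expression_group": groups.get(a.mirna_id, "noData"),
            }
        )
    return pd.DataFrame(rows)


def _profile_frame(profile) -> pd.DataFrame:
    return pd.DataFrame(
        {"offset": profile.offsets, "mean": profile.mean,
         "n": profile.n_features}
    )


def _stat_row(label: str, r: StatResult) -> dict:
    return {
        "comparison": label,
        "method": r.method,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "n": r.n,
        "m": r.m if r.m is not None else "",
        "alternative": r.alternative,
        "exact": r.exact,
    }


def run_all(config: RunConfig) -> dict:
    """Run the whole study and write report tables; returns the manifest."""
    inputs = load_inputs(config)
    return run_study(inputs, config)


def run_study(inputs: StudyInputs, config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    rng_seed = config.seed

    annotations = annotate(
        inputs.loci, inputs.genes, inputs.expression, inputs.calls,
        search_span=config.search_span,
    )
    try:
        groups = expression_groups(annotations)
    except ValidationError:
        groups = {}
        logger.warning("too few expressed miRNAs for expression quintiles")
    ann_df = _annotations_frame(annotations, groups)

    chrom_lengths = {c: inputs.genome.length(c) for c in inputs.genome.chromosomes}

    # core occupancy per miRNA (reported alongside the annotation table)
    from .genomic_io import GenomicInterval

    core_scores = {}
    half = params.core_width // 2
    for a in annotations:
        c = center_of(a.locus)
        core_scores[a.mirna_id] = core_mean(
            inputs.occupancy,
            GenomicInterval(a.locus.chrom, c - half, c + half, a.locus.strand),
            params,
        )
    ann_df["core_occupancy"] = [core_scores[m] for m in ann_df["mirna_id"]]
    ann_df.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    group_axes = {
        "positional": lambda a: a.positional_class,
        "expression": lambda a: a.expression_class,
        "promoter": lambda a: a.promoter_class,
        "expression_group": lambda a: groups.get(a.mirna_id, "noData"),
    }
    tracks = {"occupancy": inputs.occupancy, **inputs.marks}

    profile_files = []
    for track_label, track in tracks.items():
        all_prof = annotation_profile(annotations, track, params)
        path = outdir / f"profile_{track_label}_all.tsv"
        _profile_frame(all_prof).to_csv(path, sep="\t", index=False)
        profile_files.append(path.name)
        for axis, key in group_axes.items():
            for value in sorted({key(a) for a in annotations}):
                members = [a for a in annotations if key(a) == value]
                if not members:
                    continue
                prof = annotation_profile(members, track, params)
                path = outdir / f"profile_{track_label}_{axis}_{value}.tsv"
                _profile_frame(prof).to_csv(path, sep="\t", index=False)
                profile_files.append(path.name)

    content_files = []
    for pattern in CONTENT_PATTERNS:
        prof = content_metaprofile(annotations, inputs.genome, pattern, params)
        path = outdir / f"content_{pattern}.tsv"
        _profile_frame(prof).to_csv(path, sep="\t", index=False)
        content_files.append(path.name)

    bins = gc_quintile_bins(annotations, inputs.genome, inputs.occupancy, params)
    bin_rows = []
    for b in bins:
        frame = _profile_frame(b["profile"])
        frame.insert(0, "bin", b["label"])
        bin_rows.append(frame)
    pd.concat(bin_rows).to_csv(outdir / "gc_quintile_profiles.tsv", sep="\t",
                               index=False)
    bin_summary = pd.DataFrame(
        [
            {
                "bin": b["label"],
                "n": len(b["members"]),
                "gc_min": b["gc_range"][0],
                "gc_max": b["gc_range"][1],
                "mean_gc": b["mean_gc"],
                "mean_core_occupancy": float(
                    np.mean([core_scores[a.mirna_id] for a in b["members"]])
                ),
            }
            for b in bins
        ]
    )
    bin_summary.to_csv(outdir / "gc_quintile_summary.tsv", sep="\t", index=False)

    stat_rows = []
    window_sets, excluded = build_window_sets(
        annotations, params, config.flank_gap, chrom_lengths
    )
    ws_by_id = {w.feature_id: w for w in window_sets}
    for track_label, track in tracks.items():
        for axis, key in (("all", None), *group_axes.items()):
            subsets = (
                {"all": annotations}
                if key is None
                else {
                    v: [a for a in annotations if key(a) == v]
                    for v in sorted({key(a) for a in annotations})
                }
            )
            for value, members in subsets.items():
                sets = [ws_by_id[a.mirna_id] for a in members if a.mirna_id in ws_by_id]
                pairs, skipped = paired_core_scores(sets, track, params)
                if len(pairs) < 2:
                    continue
                res = wilcoxon_signed_rank(
                    np.array([p[1] for p in pairs]), np.array([p[2] for p in pairs])
                )
                stat_rows.append(
                    _stat_row(f"center-vs-flank:{track_label}:{axis}={value}", res)
                )

    # group-vs-group comparisons of core occupancy
    for axis, key in group_axes.items():
        values = sorted({key(a) for a in annotations})
        for i, va in enumerate(values):
            for vb in values[i + 1 :]:
                xa = np.array(
                    [core_scores[a.mirna_id] for a in annotations if key(a) == va]
                )
                xb = np.array(
                    [core_scores[a.mirna_id] for a in annotations if key(a) == vb]
                )
                if xa.size == 0 or xb.size == 0:
                    continue
                res = rank_sum_test(xa, xb)
                stat_rows.append(_stat_row(f"group:{axis}:{va}-vs-{vb}", res))

    # occupancy vs expression association
    expr_levels = np.array([a.expression_level for a in annotations])
    occ_levels = np.array([core_scores[a.mirna_id] for a in annotations])
    kendall_row = None
    if np.unique(expr_levels).size > 1 and np.unique(occ_levels).size > 1:
        tau = kendall_tau(occ_levels, expr_levels)
        kendall_row = _stat_row("kendall:core-occupancy-vs-expression", tau)
        stat_rows.append(kendall_row)

    pd.DataFrame(stat_rows).to_csv(outdir / "stat_results.tsv", sep="\t",
                                   index=False)

    # density comparison across pre-miRNAs, exons and introns
    features_by_kind = {
        "pre-miRNA": [(a.mirna_id, a.locus) for a in annotations],
        "exon": [
            (f"{g.name}:exon{i}", e)
            for g in inputs.genes
            for i, e in enumerate(g.exons)
        ],
        "intron": [
            (f"{g.name}:intron{i}", iv)
            for g in inputs.genes
            for i, iv in enumerate(g.introns)
        ],
    }
    features_by_kind = {k: v for k, v in features_by_kind.items() if v}
    records, summaries, density_tests = occupancy_density(
        features_by_kind, inputs.occupancy
    )
    pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "kind": r.kind,
                "length": r.length,
                "occupancy_sum": r.occupancy_sum,
                "density": r.density,
            }
            for r in records
        ]
    ).to_csv(outdir / "density_records.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"kind": k, **v} for k, v in summaries.items()]
    ).to_csv(outdir / "density_summary.tsv", sep="\t", index=False)
    density_rows = [
        _stat_row(f"density:{a}-vs-{b}", r) for (a, b), r in density_tests.items()
    ]
    pd.DataFrame(density_rows).to_csv(outdir / "density_tests.tsv", sep="\t",
                                      index=False)

    edges = (
        np.asarray(config.histogram_edges, dtype=float)
        if config.histogram_edges
        else None
    )
    edges, percentages = occupancy_histogram(annotations, inputs.occupancy,
                                             params, edges)
    pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "percent": percentages,
        }
    ).to_csv(outdir / "occupancy_histogram.tsv", sep="\t", index=False)

    manifest = {
        "package": "mirchrom",
        "version": __version__,
        "seed": rng_seed,
        "params": asdict(params),
        "search_span": config.search_span,
        "flank_gap": config.flank_gap,
        "n_mirnas": len(annotations),
        "n_excluded_boundary": len(excluded),
        "group_sizes": {
            axis: {
                v: sum(1 for a in annotations if key(a) == v)
                for v in sorted({key(a) for a in annotations})
            }
            for axis, key in group_axes.items()
        },
        "tables": sorted(
            p.name for p in outdir.iterdir() if p.suffix == ".tsv"
        ),
        "kendall": kendall_row,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
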