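"""Rank-based statistical battery for the chromatin comparisons.

Paired center-vs-flank comparisons use the Wilcoxon signed-rank test
(zero differences dropped, midranks for ties; exact enumeration p-value
for tie-free samples of n <= 25, otherwise the normal approximation with
tie and continuity corrections). Unpaired group-vs-group comparisons use
the Mann-Whitney rank-sum test (exact for tie-free n+m <= 12). Monotone
association between occupancy and expression uses Kendall's tau-b with
the asymptotic normal p-value. p-values come from scipy.stats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .genomic_io import CoverageTrack, GenomicInterval, GenomeSequence
from .metaprofile import (
    MetaProfile,
    ProfileParams,
    annotation_profile,
    center_of,
    sequence_content,
)
from .windows import core_mean

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two-sided", "greater", "less")

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 12


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical comparison."""

    method: str
    statistic: float
    p_value: float
    n: int
    m: int | None = None
    alternative: str = "two-sided"
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass(frozen=True)
class DensityRecord:
    """Length-normalised occupancy of one feature."""

    feature_id: str
    kind: str  # "pre-miRNA", "exon" or "intron"
    length: int
    occupancy_sum: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"feature {self.feature_id} has no length")

    @property
    def density(self) -> float:
        return self.occupancy_sum / self.length


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> StatResult:
    """Paired Wilcoxon signed-rank test of x against y.

    Zero differences are dropped; the reported statistic is W+ (sum of the
    midranks of the positive differences). When all differences are zero
    the result degenerates to p = 1 with a warning.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("paired samples must be equal-length 1-d arrays")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        logger.warning("all paired differences are zero; degenerate p = 1")
        return StatResult(
            "wilcoxon-signed-rank", 0.0, 1.0, x.size, None, alternative, False
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    tie_free = np.unique(np.abs(d)).size == d.size
    exact = tie_free and d.size <= EXACT_SIGNED_RANK_MAX_N
    res = sps.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative=alternative,
        method="exact" if exact else "approx",
    )
    return StatResult(
        "wilcoxon-signed-rank",
        w_plus,
        float(res.pvalue),
        int(d.size),
        None,
        alternative,
        exact,
    )


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> StatResult:
    """Mann-Whitney U rank-sum test of x against y (statistic = U of x)."""
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    exact = tie_free and combined.size <= EXACT_RANK_SUM_MAX_N
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return StatResult(
        "mann-whitney-rank-sum",
        float(res.statistic),
        float(res.pvalue),
        int(x.size),
        int(y.size),
        alternative,
        exact,
    )


def kendall_tau(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Kendall's tau-b rank correlation with asymptotic normal p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("kendall_tau requires equal-length arrays, n >= 2")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("tau undefined: a sample has zero variance")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return StatResult(
        "kendall-tau-b",
        float(res.statistic),
        float(res.pvalue),
        int(x.size),
        None,
        "two-sided",
        False,
    )


def _split_sizes(n: int, k: int) -> list[int]:
    """k contiguous chunk sizes differing by <=1, remainder to the first."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def gc_quintile_bins(
    annotations,
    sequences: GenomeSequence,
    track: CoverageTrack,
    params: ProfileParams = ProfileParams(),
    n_bins: int = 5,
) -> list[dict]:
    """Bin loci by core-window GC content and profile occupancy per bin.

    Each locus is scored by the GC fraction of the core_width (400-nt)
    window around its center; loci are sorted ascending and split into
    ``n_bins`` contiguous bins whose sizes differ by at most one (extra
    members go to the lowest-GC bins). Returns one dict per bin with keys
    ``label``, ``members``, ``gc_range``, ``mean_gc`` and ``profile``
    (a MetaProfile of the occupancy in that bin).
    """
    if len(annotations) < n_bins:
        raise ValidationError(f"need >= {n_bins} features for {n_bins} bins")
    half = params.core_width // 2
    scored = []
    for ann in annotations:
        locus = ann.locus
        c = center_of(locus)
        seq = sequences.fetch_padded(locus.chrom, c - half, c + half)
        scored.append((sequence_content(seq, "gc"), ann.mirna_id, ann))
    scored.sort(key=lambda t: (t[0], t[1]))  # id tie-break: order-independent
    labels = (
        ["lowest", "low", "medium", "high", "highest"]
        if n_bins == 5
        else [f"bin{i + 1}" for i in range(n_bins)]
    )
    bins = []
    pos = 0
    for label, size in zip(labels, _split_sizes(len(scored), n_bins)):
        chunk = scored[pos : pos + size]
        pos += size
        members = [ann for _, _, ann in chunk]
        scores = [s for s, _, _ in chunk]
        bins.append(
            {
                "label": label,
                "members": members,
                "gc_range": (min(scores), max(scores)),
                "mean_gc": float(np.mean(scores)),
                "profile": annotation_profile(members, track, params),
            }
        )
    return bins


def occupancy_density(
    features_by_kind: dict[str, list[tuple[str, GenomicInterval]]],
    track: CoverageTrack,
) -> tuple[list[DensityRecord], dict[str, dict], dict[tuple[str, str], StatResult]]:
    """Length-normalised occupancy per feature, with per-kind comparisons.

    Returns (records, per-kind summaries, pairwise rank-sum results).
    Summaries report n, mean and quartiles of the density distribution.
    """
    if not any(features_by_kind.values()):
        raise ValidationError("no features supplied")
    records = []
    for kind, features in features_by_kind.items():
        for feature_id, iv in features:
            records.append(
                DensityRecord(feature_id, kind, iv.length, track.interval_sum(iv))
            )
    summaries: dict[str, dict] = {}
    densities: dict[str, np.ndarray] = {}
    for kind in features_by_kind:
        vals = np.array([r.density for r in records if r.kind == kind])
        densities[kind] = vals
        if vals.size:
            q1, q2, q3 = np.percentile(vals, [25, 50, 75])
            summaries[kind] = {
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "q1": float(q1),
                "median": float(q2),
                "q3": float(q3),
            }
    tests: dict[tuple[str, str], StatResult] = {}
    kinds = [k for k, v in densities.items() if v.size > 0]
    for i, a in enumerate(kinds):
        for b in kinds[i + 1 :]:
            tests[(a, b)] = rank_sum_test(densities[a], densities[b])
    return records, summaries, tests


def occupancy_histogram(
    annotations,
    track: CoverageTrack,
    params: ProfileParams = ProfileParams(),
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of miRNAs per bin of core-window mean occupancy.

    Scores are the mean occupancy over the core_width window around each
    locus center. The final bin is right-closed, so percentages sum to
    100 whenever all scores fall within the edges. Returns
    (bin_edges, percentages).
    """
    if not annotations:
        raise ValidationError("occupancy_histogram requires features")
    scores = np.array(
        [
            core_mean(
                track,
                GenomicInterval(
                    a.locus.chrom,
                    center_of(a.locus) - params.core_width // 2,
                    center_of(a.locus) + params.core_width // 2,
                    a.locus.strand,
                ),
                params,
            )
            for a in annotations
        ]
    )
    if bin_edges is None:
        bin_edges = np.linspace(0.0, max(scores.max(), 1e-9), 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing, >= 2 values")
    counts, _ = np.histogram(scores, bins=bin_edges)
    dropped = scores.size - counts.sum()
    if dropped:
        warnings.warn(f"{dropped} scores fall outside the histogram edges")
    return bin_edges, 100.0 * counts / scores.size
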