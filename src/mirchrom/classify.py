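"""Classification of pre-miRNA loci along three independent axes.

Positional class compares each locus against protein-coding gene models:
any exon overlap (>=1 bp) makes the locus *exonic*; otherwise full
containment in an intron makes it *intronic* (host gene and intron are
recorded); anything else is *intergenic*.

Expression class is binary: a miRNA is *expressed* iff deep-sequencing
reads were detected for it (read count > 0); ids absent from the table
count as unexpressed.

Promoter class scans the 250,000-nt region upstream (strand-aware) of the
locus for enrichment calls of RNAPII, H3K4me3 and H2A.Z. The promoter is
*active* iff all three marks have a call in the search region AND either
an RNAPII call co-localizes with an H2A.Z and/or H3K4me3 call, or an
H3K4me3 call co-localizes with an H2A.Z call. A miRNA that is not active
and not expressed has an *inactive* promoter; an expressed miRNA without
an identified active promoter is *unidentified*. The classes are
independent axes, not a partition: a locus can be, say, exonic, expressed
and inactive simultaneously.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genomic_io import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

PROMOTER_MARKS = ("RNAPII", "H3K4me3", "H2A.Z")

POSITIONAL_CLASSES = ("intronic", "intergenic", "exonic")
EXPRESSION_CLASSES = ("expressed", "unexpressed")
PROMOTER_CLASSES = ("active", "inactive", "unidentified")

DEFAULT_SEARCH_SPAN = 250_000


@dataclass(frozen=True)
class EnrichmentCall:
    """A called enrichment interval for one of the three promoter marks."""

    mark: str
    region: GenomicInterval

    def __post_init__(self) -> None:
        if self.mark not in PROMOTER_MARKS:
            raise ValidationError(
                f"unknown enrichment mark {self.mark!r}; "
                f"expected one of {PROMOTER_MARKS}"
            )


@dataclass
class MiRNAAnnotation:
    """A pre-miRNA locus together with its three derived class labels."""

    mirna_id: str
    locus: GenomicInterval
    positional_class: str
    host_gene: str | None = None
    host_intron: GenomicInterval | None = None
    expression_class: str = "unexpressed"
    promoter_class: str = "unidentified"
    expression_level: float = 0.0

    def __post_init__(self) -> None:
        if self.positional_class not in POSITIONAL_CLASSES:
            raise ValidationError(
                f"invalid positional class {self.positional_class!r}"
            )
        if self.positional_class == "intronic" and self.host_intron is None:
            raise ValidationError("intronic annotation requires a host intron")
        if self.positional_class == "intergenic" and self.host_gene is not None:
            raise ValidationError("intergenic annotation cannot have a host gene")
        if (self.expression_level > 0) != (self.expression_class == "expressed"):
            raise ValidationError(
                "expression_class must be 'expressed' iff expression_level > 0"
            )


class _GeneIndex:
    """Sorted per-chromosome exon/intron lookup used by classify_position."""

    def __init__(self, genes: list[GeneModel]):
        self._exons: dict[str, tuple[list[int], list[tuple[int, int, str]]]] = {}
        self._introns: dict[str, tuple[list[int], list]] = {}
        exons_by_chrom: dict[str, list] = {}
        introns_by_chrom: dict[str, list] = {}
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span.start, g.name)):
            for exon in gene.exons:
                exons_by_chrom.setdefault(gene.chrom, []).append(
                    (exon.start, exon.end, gene.name)
                )
            for intron in gene.introns:
                introns_by_chrom.setdefault(gene.chrom, []).append(
                    (intron.start, intron.end, gene.name, intron)
                )
        for chrom, items in exons_by_chrom.items():
            items.sort()
            self._exons[chrom] = ([it[0] for it in items], items)
        for chrom, items in introns_by_chrom.items():
            items.sort(key=lambda it: (it[0], it[1], it[2]))
            self._introns[chrom] = ([it[0] for it in items], items)
        self.chromosomes = set(exons_by_chrom)
        self._warned_chroms: set[str] = set()

    def overlapping_exon_gene(self, locus: GenomicInterval) -> str | None:
        if locus.chrom not in self._exons:
            return None
        starts, items = self._exons[locus.chrom]
        # any exon with start < locus.end could overlap; scan left for end > start
        hi = bisect_right(starts, locus.end - 1)
        best: tuple[int, str] | None = None
        for start, end, gene in items[:hi]:
            if end > locus.start and (best is None or (start, gene) < best):
                best = (start, gene)
        return best[1] if best else None

    def containing_intron(
        self, locus: GenomicInterval
    ) -> tuple[str, GenomicInterval] | None:
        if locus.chrom not in self._introns:
            return None
        starts, items = self._introns[locus.chrom]
        hi = bisect_right(starts, locus.start)
        for start, end, gene, intron in items[:hi]:
            if end >= locus.end:
                return gene, intron
        return None


def classify_position(
    locus: GenomicInterval, gene_models: list[GeneModel] | _GeneIndex
) -> tuple[str, str | None, GenomicInterval | None]:
    """Assign intronic / intergenic / exonic by overlap with gene models.

    Returns ``(positional_class, host_gene, host_intron)``. Exon overlap
    takes precedence; ties between overlapping genes break to the first
    gene in (start, name) order. A locus on a chromosome absent from the
    gene models is intergenic (with a logged warning).
    """
    index = gene_models if isinstance(gene_models, _GeneIndex) else _GeneIndex(gene_models)
    if locus.chrom not in index.chromosomes:
        if locus.chrom not in index._warned_chroms:
            index._warned_chroms.add(locus.chrom)
            logger.warning(
                "chromosome %s absent from gene models; its loci are intergenic",
                locus.chrom,
            )
        return "intergenic", None, None
    exon_gene = index.overlapping_exon_gene(locus)
    if exon_gene is not None:
        return "exonic", exon_gene, None
    hit = index.containing_intron(locus)
    if hit is not None:
        gene, intron = hit
        return "intronic", gene, intron
    return "intergenic", None, None


def build_gene_index(gene_models: list[GeneModel]) -> _GeneIndex:
    """Pre-build the sorted lookup when classifying many loci."""
    return _GeneIndex(gene_models)


def classify_expression(
    mirna_id: str, expression: dict[str, float]
) -> tuple[str, float]:
    """Expressed iff reads were detected; absent ids count as zero reads."""
    level = float(expression.get(mirna_id, 0.0))
    return ("expressed" if level > 0 else "unexpressed"), level


def upstream_region(
    locus: GenomicInterval, search_span: int = DEFAULT_SEARCH_SPAN
) -> GenomicInterval | None:
    """The strand-aware upstream search window, clipped at position 0.

    Unstranded loci default to the + convention (upstream = lower
    coordinates) with a warning. Returns None when the locus abuts the
    chromosome start on the + strand (no upstream sequence exists).
    """
    strand = locus.strand
    if strand == ".":
        logger.warning("unstranded locus %s: assuming + strand for upstream", locus)
        strand = "+"
    if strand == "+":
        if locus.start == 0:
            return None
        return GenomicInterval(
            locus.chrom, max(0, locus.start - search_span), locus.start, "+"
        )
    return GenomicInterval(locus.chrom, locus.end, locus.end + search_span, "-")


def _clip(region: GenomicInterval, call: GenomicInterval) -> tuple[int, int] | None:
    lo = max(region.start, call.start)
    hi = min(region.end, call.end)
    return (lo, hi) if lo < hi else None


def classify_promoter(
    locus: GenomicInterval,
    calls: list[EnrichmentCall],
    expression_class: str,
    search_span: int = DEFAULT_SEARCH_SPAN,
    colocalize_max_gap: int = 0,
) -> str:
    """Apply the three-mark co-localization rule in the upstream window.

    Calls are clipped to the upstream region before the pairwise overlap
    test, so only in-window co-localization counts. ``colocalize_max_gap``
    relaxes "overlap by >=1 bp" to "within that many bp" when positive.
    """
    if expression_class not in EXPRESSION_CLASSES:
        raise ValidationError(f"invalid expression class {expression_class!r}")
    region = upstream_region(locus, search_span)
    in_window: dict[str, list[tuple[int, int]]] = {m: [] for m in PROMOTER_MARKS}
    if region is not None:
        for call in calls:
            if call.region.chrom != region.chrom:
                continue
            clipped = _clip(region, call.region)
            if clipped is not None:
                in_window[call.mark].append(clipped)

    def colocalized(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
        return any(
            (lo1 - colocalize_max_gap) < hi2 and (lo2 - colocalize_max_gap) < hi1
            for lo1, hi1 in a
            for lo2, hi2 in b
        )

    all_present = all(in_window[m] for m in PROMOTER_MARKS)
    if all_present:
        rnap, k4, h2az = (in_window[m] for m in PROMOTER_MARKS)
        if colocalized(rnap, h2az) or colocalized(rnap, k4) or colocalized(k4, h2az):
            return "active"
    return "inactive" if expression_class == "unexpressed" else "unidentified"


def annotate(
    loci: list[tuple[str, GenomicInterval]],
    gene_models: list[GeneModel],
    expression: dict[str, float],
    calls: list[EnrichmentCall],
    search_span: int = DEFAULT_SEARCH_SPAN,
    colocalize_max_gap: int = 0,
) -> list[MiRNAAnnotation]:
    """Run all three classifications over a set of named loci."""
    index = build_gene_index(gene_models)
    annotations = []
    for mirna_id, locus in loci:
        pos_class, host_gene, host_intron = classify_position(locus, index)
        expr_class, level = classify_expression(mirna_id, expression)
        prom_class = classify_promoter(
            locus, calls, expr_class, search_span, colocalize_max_gap
        )
        annotations.append(
            MiRNAAnnotation(
                mirna_id=mirna_id,
                locus=locus,
                positional_class=pos_class,
                host_gene=host_gene,
                host_intron=host_intron,
                expression_class=expr_class,
                promoter_class=prom_class,
                expression_level=level,
            )
        )
    return annotations


def expression_groups(
    annotations: list[MiRNAAnnotation], k: int = 5
) -> dict[str, str]:
    """Split miRNAs into a zero-read group plus k-1 expression quantiles.

    All zero-level miRNAs form the "lowest" group; the positive-level
    miRNAs are sorted ascending by read count and split into k-1
    contiguous groups whose sizes differ by at most one (remainder
    members go to the lower-expression groups).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    zero = [a for a in annotations if a.expression_level == 0]
    positive = sorted(
        (a for a in annotations if a.expression_level > 0),
        key=lambda a: (a.expression_level, a.mirna_id),
    )
    if len(positive) < k - 1:
        raise ValidationError(
            f"need >= {k - 1} miRNAs with positive expression, got {len(positive)}"
        )
    labels = {a.mirna_id: "lowest" for a in zero}
    group_names = (
        ["low", "medium", "high", "highest"]
        if k == 5
        else [f"q{i + 1}" for i in range(k - 1)]
    )
    for name, chunk in zip(group_names, np.array_split(positive, k - 1)):
        for ann in chunk:
            labels[ann.mirna_id] = name
    return labels
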