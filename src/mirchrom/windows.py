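"""Center and flanking control windows for paired chromatin comparisons.

Each locus gets a 2,000-nt *center window* around its midpoint. Flanking
control windows of the same width are selected by positional class:

* intronic loci — full windows are tiled outward from both center-window
  boundaries until the host intron's splice sites; partial windows are
  discarded, so every flank lies wholly inside the host intron.
* intergenic and exonic loci — the two windows immediately adjacent to the
  center window's boundaries (``flank_gap`` inserts a gap when positive).

The paired statistic compares the mean signal over the 400-nt core of the
center window against the mean of the flank windows' 400-nt cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import MiRNAAnnotation
from .errors import ValidationError
from .genomic_io import CoverageTrack, GenomicInterval
from .metaprofile import ProfileParams, center_of

logger = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """Center window plus flanking control windows for one feature."""

    feature_id: str
    center_window: GenomicInterval
    flank_windows: list[GenomicInterval]
    provenance: str  # "intronic-tiled" or "two-flank"

    def __post_init__(self) -> None:
        if self.provenance not in ("intronic-tiled", "two-flank"):
            raise ValidationError(f"invalid provenance {self.provenance!r}")
        width = self.center_window.length
        for w in self.flank_windows:
            if w.length != width:
                raise ValidationError("flank window width differs from center")
            if w.overlaps(self.center_window):
                raise ValidationError("flank window overlaps center window")


def center_window(
    feature: GenomicInterval, params: ProfileParams = ProfileParams()
) -> GenomicInterval:
    """The window_width window around the feature midpoint."""
    half = params.window_width // 2
    center = center_of(feature)
    if center < half:
        raise ValidationError(
            f"center window for {feature} extends past chromosome start"
        )
    return GenomicInterval(feature.chrom, center - half, center + half, feature.strand)


def flanking_windows(
    annotation: MiRNAAnnotation,
    params: ProfileParams = ProfileParams(),
    flank_gap: int = 0,
    chrom_length: int | None = None,
) -> list[GenomicInterval]:
    """Class-dependent flanking control windows for one annotated locus.

    Returned outward from the center on each side (left flanks first).
    Windows extending past position 0, past ``chrom_length`` (when given)
    or, for intronic loci, past the host intron are dropped.
    """
    cw = center_window(annotation.locus, params)
    width = params.window_width
    chrom, strand = cw.chrom, cw.strand

    def in_bounds(start: int, end: int) -> bool:
        return start >= 0 and (chrom_length is None or end <= chrom_length)

    windows: list[GenomicInterval] = []
    if annotation.positional_class == "intronic":
        intron = annotation.host_intron
        if intron is None:
            raise ValidationError(
                f"intronic locus {annotation.mirna_id} lacks a host intron"
            )
        start = cw.start - width
        while start >= intron.start:
            if in_bounds(start, start + width):
                windows.append(GenomicInterval(chrom, start, start + width, strand))
            start -= width
        end = cw.end + width
        while end <= intron.end:
            if in_bounds(end - width, end):
                windows.append(GenomicInterval(chrom, end - width, end, strand))
            end += width
        return windows

    for start in (cw.start - flank_gap - width, cw.end + flank_gap):
        if in_bounds(start, start + width):
            windows.append(GenomicInterval(chrom, start, start + width, strand))
    return windows


def build_window_sets(
    annotations: list[MiRNAAnnotation],
    params: ProfileParams = ProfileParams(),
    flank_gap: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[WindowSet], list[str]]:
    """WindowSets for all loci; returns (window_sets, excluded feature ids).

    Loci whose center window would cross a chromosome boundary are
    excluded (and reported), mirroring their exclusion from paired tests.
    """
    sets: list[WindowSet] = []
    excluded: list[str] = []
    for ann in annotations:
        length = None
        if chrom_lengths is not None:
            length = chrom_lengths.get(ann.locus.chrom)
        try:
            cw = center_window(ann.locus, params)
            if length is not None and cw.end > length:
                raise ValidationError("center window past chromosome end")
        except ValidationError:
            excluded.append(ann.mirna_id)
            continue
        flanks = flanking_windows(ann, params, flank_gap, length)
        provenance = (
            "intronic-tiled" if ann.positional_class == "intronic" else "two-flank"
        )
        sets.append(WindowSet(ann.mirna_id, cw, flanks, provenance))
    if excluded:
        logger.info("excluded %d boundary features from window sets", len(excluded))
    return sets, excluded


def core_mean(
    track: CoverageTrack,
    window: GenomicInterval,
    params: ProfileParams = ProfileParams(),
) -> float:
    """Mean score over the core_width region around the window's midpoint."""
    if window.length < params.core_width:
        raise ValidationError("window shorter than core width")
    c = center_of(window)
    half = params.core_width // 2
    return float(np.mean(track.get(window.chrom, c - half, c + half)))


def paired_core_scores(
    window_sets: list[WindowSet],
    track: CoverageTrack,
    params: ProfileParams = ProfileParams(),
    flank_agg: str = "mean",
) -> tuple[list[tuple[str, float, float]], list[str]]:
    """Per-feature (id, center core mean, aggregated flank core mean).

    Features without any flank window are skipped and reported in the
    second return value. ``flank_agg`` is ``mean`` (default) or ``median``.
    """
    if flank_agg not in ("mean", "median"):
        raise ValidationError(f"unknown flank aggregation {flank_agg!r}")
    agg = np.mean if flank_agg == "mean" else np.median
    pairs: list[tuple[str, float, float]] = []
    skipped: list[str] = []
    for ws in window_sets:
        if not ws.flank_windows:
            skipped.append(ws.feature_id)
            continue
        center_score = core_mean(track, ws.center_window, params)
        flank_score = float(
            agg([core_mean(track, w, params) for w in ws.flank_windows])
        )
        pairs.append((ws.feature_id, center_score, flank_score))
    if not pairs:
        logger.warning("all %d features skipped (no flank windows)", len(skipped))
    return pairs, skipped
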